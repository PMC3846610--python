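"""Dataset cleaning: from a raw probeset table to a classification-ready matrix.

The pipeline order is fixed:

1. ``apply_amp_calls`` — zero cells whose Absent/Marginal/Present detection
   call is A or M (microarray background-level signal is treated as no
   expression);
2. ``average_duplicates`` — arithmetic mean over replicate sample columns;
3. ``collapse_probesets`` — for genes measured by several probesets, keep
   the probeset whose profile has the largest standard deviation (the most
   informative one for pattern detection).

Collapse therefore sees exactly the values classification will see.  No
cross-sample normalisation (quantile, global scaling, ...) is performed:
columns are assumed to be on comparable scales already.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core_stats import ProfileValidationError

__all__ = [
    "RawExpressionTable",
    "apply_amp_calls",
    "average_duplicates",
    "collapse_probesets",
    "handle_missing",
    "validate_dataset",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

VALID_FLAGS = frozenset("AMP")


@dataclass
class RawExpressionTable:
    """A probeset x sample table as read from disk, before cleaning.

    ``values`` may still contain negatives and missing cells at this
    stage.  ``flags`` (optional) is a congruent matrix of A/M/P detection
    calls.  ``probeset_to_gene`` (optional) maps probeset IDs to gene
    symbols for the collapse step.  ``replicate_groups`` (optional) maps
    sample label -> group label, e.g. recovered from GDS subset
    annotations.
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None
    probeset_to_gene: Mapping[str, str] | None = None
    replicate_groups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ProfileValidationError(f"duplicate sample label {dup!r}")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise ProfileValidationError(
                    f"flag table shape {self.flags.shape} does not match "
                    f"value table shape {self.values.shape}"
                )


def apply_amp_calls(table: RawExpressionTable) -> RawExpressionTable:
    """Zero every cell flagged Absent or Marginal; Present cells pass through.

    The input table is not mutated.  Unknown flag characters raise a
    validation error naming the offending cell.
    """
    if table.flags is None:
        raise ProfileValidationError("no A/M/P flag table attached")
    flags = table.flags.astype(str).apply(lambda col: col.str.strip().str.upper())
    bad = ~flags.isin(VALID_FLAGS)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ProfileValidationError(
            f"unknown detection call {table.flags.iat[i, j]!r} at "
            f"probeset {table.values.index[i]!r}, sample {table.values.columns[j]!r}"
        )
    values = table.values.where(flags.to_numpy() == "P", 0.0)
    return replace(table, values=values, flags=flags)


def average_duplicates(
    table: RawExpressionTable, grouping: Mapping[str, str] | None = None
) -> RawExpressionTable:
    """Collapse replicate sample columns to their arithmetic mean.

    ``grouping`` maps every sample label to a group label; output columns
    are the group labels in first-appearance order.  Singleton groups pass
    through unchanged.  With no grouping (or the table's own
    ``replicate_groups``) absent, the table is returned as is.
    """
    if grouping is None:
        grouping = table.replicate_groups
    if grouping is None:
        return table
    missing = [c for c in table.values.columns if str(c) not in grouping]
    if missing:
        raise ProfileValidationError(
            f"replicate grouping missing sample(s): {missing[:5]}"
        )
    group_order: list[str] = []
    members: dict[str, list[str]] = {}
    for c in table.values.columns:
        g = str(grouping[str(c)])
        if g not in members:
            members[g] = []
            group_order.append(g)
        members[g].append(c)
    if all(len(m) == 1 for m in members.values()):
        values = table.values.copy()
        values.columns = group_order
        return replace(table, values=values, flags=None if table.flags is None else _relabel(table.flags, group_order), replicate_groups=None)
    values = pd.DataFrame(
        {g: table.values[members[g]].mean(axis=1) for g in group_order},
        index=table.values.index,
    )
    # Flags are per-hybridisation and have no meaning for an averaged column.
    return replace(table, values=values, flags=None, replicate_groups=None)


def _relabel(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = df.copy()
    out.columns = columns
    return out


def collapse_probesets(table: RawExpressionTable) -> pd.DataFrame:
    """One row per gene: keep the probeset with the largest profile SD.

    SD is the sample standard deviation (ddof=1) of the row's current
    values, i.e. after A/M/P zeroing and replicate averaging.  Ties keep
    the probeset appearing first in file order (logged).  Probesets with
    no gene mapping are dropped, with a count logged.  Every output row is
    an input row verbatim — collapse never invents values.
    """
    if not table.probeset_to_gene:
        raise ProfileValidationError("probeset-to-gene mapping is empty or missing")
    mapping = {str(k): str(v) for k, v in table.probeset_to_gene.items()}
    unmapped = 0
    chosen: dict[str, tuple[float, str]] = {}  # gene -> (sd, probeset)
    gene_order: list[str] = []
    ties = 0
    sds = table.values.std(axis=1, ddof=1)
    for probeset in table.values.index:
        gene = mapping.get(str(probeset))
        if gene is None:
            unmapped += 1
            continue
        sd = float(sds.loc[probeset])
        if gene not in chosen:
            chosen[gene] = (sd, probeset)
            gene_order.append(gene)
        elif sd > chosen[gene][0]:
            chosen[gene] = (sd, probeset)
        elif sd == chosen[gene][0]:
            ties += 1
    if unmapped:
        logger.info("%d unmapped probeset(s) dropped during collapse", unmapped)
    if ties:
        logger.info("%d SD tie(s) during collapse; first probeset in file order kept", ties)
    matrix = pd.DataFrame(
        [table.values.loc[chosen[g][1]].to_numpy(dtype=float) for g in gene_order],
        index=pd.Index(gene_order, name="gene_id"),
        columns=table.values.columns,
    )
    return matrix


def handle_missing(table: RawExpressionTable, *, impute_zero: bool = False) -> RawExpressionTable:
    """Resolve missing cells: drop incomplete rows (default) or impute 0."""
    if not table.values.isna().to_numpy().any():
        return table
    if impute_zero:
        values = table.values.fillna(0.0)
        return replace(table, values=values)
    keep = ~table.values.isna().any(axis=1)
    dropped = int((~keep).sum())
    logger.info("%d row(s) with missing cells dropped", dropped)
    values = table.values.loc[keep]
    flags = None if table.flags is None else table.flags.loc[keep]
    return replace(table, values=values, flags=flags)


def validate_dataset(matrix: pd.DataFrame) -> list[str]:
    """Non-fatal quality warnings on a finished matrix; never blocks computation.

    Mirrors the usual dataset-selection expectations: at least 5 distinct
    samples, no all-zero genes, nonnegative values.
    """
    warnings_list: list[str] = []
    if matrix.shape[1] < 5:
        warnings_list.append(
            f"fewer than 5 samples ({matrix.shape[1]}); pattern statistics are weakly informative"
        )
    values = matrix.to_numpy(dtype=float)
    n_zero = int((~(values > 0).any(axis=1)).sum())
    if n_zero:
        warnings_list.append(f"{n_zero} all-zero gene(s) will be skipped by classification")
    if (values < 0).any():
        warnings_list.append(
            "negative values present; enable negative clamping or check the data scale"
        )
    return warnings_list


def preprocess_pipeline(
    table: RawExpressionTable,
    *,
    grouping: Mapping[str, str] | None = None,
    impute_zero: bool = False,
    clamp_negatives: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full cleaning pipeline; returns (matrix, warnings).

    Steps that lack their inputs are skipped: no flag table -> no A/M/P
    zeroing; no probeset map -> rows pass through under their probeset IDs
    (they must then be unique per gene already).
    """
    table = handle_missing(table, impute_zero=impute_zero)
    if table.flags is not None:
        table = apply_amp_calls(table)
    table = average_duplicates(table, grouping)
    if clamp_negatives:
        table = replace(table, values=table.values.clip(lower=0.0))
    elif (table.values.to_numpy(dtype=float) < 0).any():
        raise ProfileValidationError(
            "negative expression values present; pass clamp_negatives=True to floor at 0"
        )
    if table.probeset_to_gene:
        matrix = collapse_probesets(table)
    else:
        if table.values.index.duplicated().any():
            dup = table.values.index[table.values.index.duplicated()][0]
            raise ProfileValidationError(
                f"duplicate gene ID {dup!r} without a probeset-to-gene mapping"
            )
        matrix = table.values.astype(float).copy()
        matrix.index.name = "gene_id"
    return matrix, validate_dataset(matrix)
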