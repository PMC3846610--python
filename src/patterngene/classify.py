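"""Classification of expression profiles into the four pattern-gene classes.

Each gene is tested independently against the four rules (a gene may
therefore carry several calls, e.g. specific in one dataset and selective
in another; within one matrix overlaps are rare under the default
thresholds).  All threshold comparisons are strict (``>`` / ``<``): a
profile sitting exactly on a threshold produces no call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import core_stats
from .core_stats import UndefinedStatisticError, ProfileValidationError

__all__ = [
    "CLASS_ORDER",
    "PatternThresholds",
    "PatternCall",
    "call_specific",
    "call_housekeeping",
    "call_selective",
    "call_repressed",
    "classify_profile",
    "classify_matrix",
]

logger = logging.getLogger(__name__)

#: Deterministic emission order of the four classes within one gene.
CLASS_ORDER = ("specific", "selective", "housekeeping", "repressed")


@dataclass(frozen=True)
class PatternThresholds:
    """Classification criteria; defaults are the standard quick-search values.

    All comparisons are strict.  ``k`` ranges bound the size of the
    enriched (selective) or silenced (repressed) sample subset.
    """

    specific_spm_min: float = 0.9
    housekeeping_dpm_max: float = 0.3
    selective_k_min: int = 2
    selective_k_max: int = 6
    selective_spm_min: float = 0.3
    selective_ctm_min: float = 0.9
    repressed_k_min: int = 1
    repressed_k_max: int = 6
    repressed_spm_max: float = 0.1
    repressed_rpm_max: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "specific_spm_min",
            "housekeeping_dpm_max",
            "selective_spm_min",
            "selective_ctm_min",
            "repressed_spm_max",
            "repressed_rpm_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 1 <= self.selective_k_min <= self.selective_k_max:
            raise ValueError("selective k bounds must satisfy 1 <= k_min <= k_max")
        if not 1 <= self.repressed_k_min <= self.repressed_k_max:
            raise ValueError("repressed k bounds must satisfy 1 <= k_min <= k_max")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float | int]) -> "PatternThresholds":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown threshold name(s): {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]

    def replace(self, **kwargs) -> "PatternThresholds":
        return replace(self, **kwargs)


@dataclass
class PatternCall:
    """One pattern assertion for one gene — a row of the pattern-gene report.

    ``samples`` lists the implicated sample labels (1 for specific, k for
    selective/repressed, all for housekeeping) and ``spm_values`` their
    SPM scores, aligned.  ``scores`` holds the scalar statistics the
    class's rule tested (DPM, CTM or RPM).
    """

    gene_id: str
    pattern_class: str
    samples: tuple[str, ...]
    spm_values: tuple[float, ...]
    scores: dict[str, float] = field(default_factory=dict)
    k: int = 1
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.pattern_class not in CLASS_ORDER:
            raise ValueError(f"unknown pattern class {self.pattern_class!r}")
        if not self.samples:
            raise ValueError("a pattern call must implicate at least one sample")
        if len(self.samples) != len(self.spm_values):
            raise ValueError("samples and spm_values must align")


def _labels(values, sample_labels) -> list[str]:
    if sample_labels is None:
        return [f"S{j + 1}" for j in range(len(values))]
    labels = [str(s) for s in sample_labels]
    if len(labels) != len(values):
        raise ProfileValidationError("sample_labels length must match profile length")
    if len(set(labels)) != len(labels):
        raise ProfileValidationError("sample labels must be unique")
    return labels


def call_specific(
    values,
    thresholds: PatternThresholds = PatternThresholds(),
    *,
    gene_id: str = "",
    sample_labels=None,
    dataset_id: str = "",
) -> list[PatternCall]:
    """Specific = expressed essentially in one sample: SPM_i > threshold.

    One call per qualifying sample; under the default 0.9 at most one
    sample can qualify, because the squared SPM values sum to 1.
    """
    labels = _labels(values, sample_labels)
    s = core_stats.spm_profile(values)
    calls = []
    for i in np.flatnonzero(s > thresholds.specific_spm_min):
        calls.append(
            PatternCall(
                gene_id=gene_id,
                pattern_class="specific",
                samples=(labels[i],),
                spm_values=(float(s[i]),),
                scores={"SPM": float(s[i])},
                k=1,
                dataset_id=dataset_id,
            )
        )
    return calls


def call_housekeeping(
    values,
    thresholds: PatternThresholds = PatternThresholds(),
    *,
    gene_id: str = "",
    sample_labels=None,
    dataset_id: str = "",
    min_mean_expression: float | None = None,
) -> list[PatternCall]:
    """Housekeeping = near-uniform expression over all samples: DPM < threshold.

    The default criterion is DPM-only.  ``min_mean_expression`` adds an
    optional floor on the mean raw level, useful when picking reference
    genes, which should also be robustly detectable.
    """
    labels = _labels(values, sample_labels)
    if min_mean_expression is not None and float(np.mean(values)) < min_mean_expression:
        return []
    d = core_stats.dpm(values)
    if d < thresholds.housekeeping_dpm_max:
        s = core_stats.spm_profile(values)
        return [
            PatternCall(
                gene_id=gene_id,
                pattern_class="housekeeping",
                samples=tuple(labels),
                spm_values=tuple(float(v) for v in s),
                scores={"DPM": d},
                k=len(labels),
                dataset_id=dataset_id,
            )
        ]
    return []


def _clipped_k_range(k_min: int, k_max: int, n: int, what: str) -> range:
    # The subset must leave at least one sample outside, so k <= n - 1.
    if k_max > n - 1:
        warnings.warn(
            f"{what} k range clipped to {n - 1} for an {n}-sample profile", stacklevel=3
        )
        k_max = n - 1
    return range(k_min, k_max + 1)


def call_selective(
    values,
    thresholds: PatternThresholds = PatternThresholds(),
    *,
    gene_id: str = "",
    sample_labels=None,
    dataset_id: str = "",
    report_all_k: bool = False,
) -> list[PatternCall]:
    """Selective = enriched in k samples: top-k SPMs and their CTM pass.

    Candidate subsets are the top-k samples ranked by SPM descending
    (ties broken by column order) — any other size-k subset has a lower
    CTM.  For k from k_min upward each subset is tested for
    ``SPM_i > selective_spm_min`` (all members) and
    ``CTM > selective_ctm_min``; the call reports the smallest
    qualifying k (all qualifying k with ``report_all_k``).
    """
    labels = _labels(values, sample_labels)
    s = core_stats.spm_profile(values)
    n = s.size
    order = np.argsort(-s, kind="stable")
    calls = []
    for k in _clipped_k_range(thresholds.selective_k_min, thresholds.selective_k_max, n, "selective"):
        if k < 1 or k > n - 1:
            continue
        top = order[:k]
        if not (s[top] > thresholds.selective_spm_min).all():
            continue
        c = core_stats.ctm_from_spm(s[top])
        if c > thresholds.selective_ctm_min:
            calls.append(
                PatternCall(
                    gene_id=gene_id,
                    pattern_class="selective",
                    samples=tuple(labels[i] for i in top),
                    spm_values=tuple(float(s[i]) for i in top),
                    scores={"CTM": c},
                    k=k,
                    dataset_id=dataset_id,
                )
            )
            if not report_all_k:
                break
    return calls


def call_repressed(
    values,
    thresholds: PatternThresholds = PatternThresholds(),
    *,
    gene_id: str = "",
    sample_labels=None,
    dataset_id: str = "",
    report_all_k: bool = False,
) -> list[PatternCall]:
    """Repressed = near-silent in k samples: bottom-k SPMs and their RPM pass.

    Candidate subsets are the bottom-k samples ranked by SPM ascending
    (ties by column order).  A k whose expression group still contains a
    zero leaves RPM undefined and is passed over; if no k qualifies for
    that reason the gene is skipped with a log record.
    """
    labels = _labels(values, sample_labels)
    s = core_stats.spm_profile(values)
    n = s.size
    order = np.argsort(s, kind="stable")
    calls = []
    undefined_seen = False
    for k in _clipped_k_range(thresholds.repressed_k_min, thresholds.repressed_k_max, n, "repressed"):
        if k < 1 or k > n - 1:
            continue
        bottom = order[:k]
        if not (s[bottom] < thresholds.repressed_spm_max).all():
            continue
        try:
            r = core_stats.rpm(values, bottom)
        except UndefinedStatisticError:
            undefined_seen = True
            continue
        if r < thresholds.repressed_rpm_max:
            calls.append(
                PatternCall(
                    gene_id=gene_id,
                    pattern_class="repressed",
                    samples=tuple(labels[i] for i in bottom),
                    spm_values=tuple(float(s[i]) for i in bottom),
                    scores={"RPM": r},
                    k=k,
                    dataset_id=dataset_id,
                )
            )
            if not report_all_k:
                break
    if not calls and undefined_seen:
        logger.info(
            "gene %s: RPM undefined for every candidate k (zeros beyond the k range); "
            "no repressed call",
            gene_id or "<unnamed>",
        )
    return calls


def classify_profile(
    values,
    thresholds: PatternThresholds = PatternThresholds(),
    *,
    gene_id: str = "",
    sample_labels=None,
    dataset_id: str = "",
    report_all_k: bool = False,
) -> list[PatternCall]:
    """All four rules on one profile, in class order."""
    kw = dict(gene_id=gene_id, sample_labels=sample_labels, dataset_id=dataset_id)
    return (
        call_specific(values, thresholds, **kw)
        + call_selective(values, thresholds, report_all_k=report_all_k, **kw)
        + call_housekeeping(values, thresholds, **kw)
        + call_repressed(values, thresholds, report_all_k=report_all_k, **kw)
    )


def classify_matrix(
    matrix: pd.DataFrame,
    thresholds: PatternThresholds = PatternThresholds(),
    *,
    dataset_id: str = "",
    report_all_k: bool = False,
) -> list[PatternCall]:
    """Classify every gene (row) of a genes x samples matrix.

    All-zero genes are skipped with a log record.  Output order is
    deterministic: input gene order, then the fixed class order.
    """
    if matrix.size == 0:
        raise ProfileValidationError("empty expression matrix")
    labels = [str(c) for c in matrix.columns]
    calls: list[PatternCall] = []
    skipped = 0
    for gene_id, row in matrix.iterrows():
        values = row.to_numpy(dtype=float)
        if not (values > 0).any():
            logger.info("gene %s: all-zero profile skipped", gene_id)
            skipped += 1
            continue
        calls.extend(
            classify_profile(
                values,
                thresholds,
                gene_id=str(gene_id),
                sample_labels=labels,
                dataset_id=dataset_id,
                report_all_k=report_all_k,
            )
        )
    if skipped:
        logger.info("%d all-zero gene(s) skipped", skipped)
    return calls
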