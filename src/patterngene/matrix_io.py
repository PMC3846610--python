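"""Readers and writers: expression TSV/CSV, GEO SOFT GDS tables, reports, thresholds.

The pattern-gene report mirrors the columns of a pattern-gene table:
gene, pattern class, dataset, implicated samples with their SPM values,
the scalar statistic the rule tested (DPM, CTM or RPM) and k.  TSV output
renders numbers with 2 decimals for display; JSON keeps full precision
and round-trips exactly.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .classify import CLASS_ORDER, PatternCall, PatternThresholds
from .core_stats import ProfileValidationError
from .preprocess import RawExpressionTable

__all__ = [
    "read_expression_tsv",
    "read_probe_map",
    "read_grouping",
    "read_gds_soft",
    "write_report",
    "read_report",
    "read_thresholds",
]

#: Cell contents treated as missing in expression tables.
MISSING_TOKENS = frozenset({"", "NA", "N/A", "NAN", "NULL", "NONE"})

REPORT_COLUMNS = [
    "gene_id",
    "pattern_class",
    "dataset_id",
    "k",
    "samples",
    "spm_values",
    "DPM",
    "CTM",
    "RPM",
]


def _sniff_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_cell(text: str, *, path: Path, line: int, column: str) -> float:
    token = text.strip()
    if token.upper() in MISSING_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ProfileValidationError(
            f"{path}:{line}: non-numeric cell {text!r} in column {column!r}"
        ) from None


def read_expression_tsv(
    path,
    *,
    flags_path=None,
    probe_map_path=None,
    delimiter: str | None = None,
) -> RawExpressionTable:
    """Read a delimited expression table (first column IDs, header of sample labels).

    Missing cells ('' / NA / null) are recorded as missing, never as 0;
    ragged rows, duplicate sample labels and non-numeric cells raise
    descriptive errors with line numbers.  ``flags_path`` attaches a
    congruent A/M/P call table in the same layout; ``probe_map_path`` a
    two-column probeset -> gene map.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ProfileValidationError(f"{path}: empty file") from None
        samples = [c.strip() for c in header[1:]]
        if not samples:
            raise ProfileValidationError(f"{path}:1: header has no sample columns")
        seen: set[str] = set()
        for s in samples:
            if s in seen:
                raise ProfileValidationError(f"{path}:1: duplicate sample label {s!r}")
            seen.add(s)
        ids: list[str] = []
        data: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(samples) + 1:
                raise ProfileValidationError(
                    f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(row)}"
                )
            ids.append(row[0].strip())
            data.append(
                [
                    _parse_cell(cell, path=path, line=lineno, column=samples[j])
                    for j, cell in enumerate(row[1:])
                ]
            )
    values = pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=samples)

    flags = None
    if flags_path is not None:
        flags = _read_flag_table(Path(flags_path), delimiter=delimiter)
        if list(flags.columns) != samples or list(flags.index) != ids:
            raise ProfileValidationError(
                f"{flags_path}: flag table labels do not match the expression table"
            )
    probe_map = read_probe_map(probe_map_path) if probe_map_path is not None else None
    return RawExpressionTable(values=values, flags=flags, probeset_to_gene=probe_map)


def _read_flag_table(path: Path, *, delimiter: str | None = None) -> pd.DataFrame:
    delim = delimiter or _sniff_delimiter(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        samples = [c.strip() for c in header[1:]]
        ids, data = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(samples) + 1:
                raise ProfileValidationError(
                    f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(row)}"
                )
            ids.append(row[0].strip())
            data.append([c.strip() for c in row[1:]])
    return pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=samples)


def read_probe_map(path) -> dict[str, str]:
    """Two-column (probeset, gene) TSV -> dict."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ProfileValidationError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            probe, gene = parts[0].strip(), parts[1].strip()
            if probe and gene:
                mapping[probe] = gene
    if not mapping:
        raise ProfileValidationError(f"{path}: no probeset-to-gene pairs found")
    return mapping


def read_grouping(path) -> dict[str, str]:
    """Two-column (sample, group) TSV -> replicate grouping dict."""
    path = Path(path)
    grouping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ProfileValidationError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            grouping[parts[0].strip()] = parts[1].strip()
    if not grouping:
        raise ProfileValidationError(f"{path}: no sample-to-group pairs found")
    return grouping


def read_gds_soft(path) -> RawExpressionTable:
    """Read a GEO SOFT GDS full table into a raw expression table.

    The ``ID_REF`` column gives probeset IDs and ``IDENTIFIER`` the gene
    symbols (kept as the probeset -> gene map).  Any column whose header
    ends with ``call`` (case-insensitive) is treated as the detection-call
    column of the nearest preceding value column.  ``^SUBSET`` annotations
    are retained as a candidate replicate grouping (sample -> subset
    description).  A table that opens but never closes raises an error
    rather than silently returning a partial read.
    """
    path = Path(path)
    subsets: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    in_table = False
    table_closed = False
    subset_desc: str | None = None
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("^SUBSET"):
                subset_desc = None
            elif line.startswith("!subset_description"):
                subset_desc = line.split("=", 1)[1].strip()
            elif line.startswith("!subset_sample_id"):
                sample_ids = line.split("=", 1)[1].strip()
                for sid in sample_ids.split(","):
                    subsets[sid.strip()] = subset_desc or sample_ids
            elif line.startswith("!dataset_table_begin"):
                in_table = True
            elif line.startswith("!dataset_table_end"):
                table_closed = True
                in_table = False
            elif in_table:
                if header is None:
                    header = line.split("\t")
                elif line.strip():
                    rows.append(line.split("\t"))
    if header is None:
        raise ProfileValidationError(f"{path}: no dataset table found (malformed SOFT file)")
    if not table_closed:
        raise ProfileValidationError(f"{path}: truncated SOFT file (table never closed)")
    if header[0].upper() != "ID_REF":
        raise ProfileValidationError(f"{path}: dataset table must start with ID_REF")

    has_identifier = len(header) > 1 and header[1].upper() == "IDENTIFIER"
    first_value_col = 2 if has_identifier else 1
    value_cols: list[int] = []
    call_for_value: dict[int, int] = {}
    for j in range(first_value_col, len(header)):
        if header[j].strip().lower().endswith("call"):
            if value_cols:
                call_for_value[value_cols[-1]] = j
        else:
            value_cols.append(j)

    ids, gene_map, data, flag_data = [], {}, [], []
    sample_labels = [header[j] for j in value_cols]
    for lineno, row in enumerate(rows, start=1):
        if len(row) != len(header):
            raise ProfileValidationError(
                f"{path}: table row {lineno} has {len(row)} fields, expected {len(header)}"
            )
        probe = row[0].strip()
        ids.append(probe)
        if has_identifier:
            gene_map[probe] = row[1].strip()
        data.append(
            [
                _parse_cell(row[j], path=path, line=lineno, column=header[j])
                for j in value_cols
            ]
        )
        if call_for_value:
            flag_data.append([row[call_for_value[j]].strip() if j in call_for_value else "P" for j in value_cols])

    values = pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=sample_labels)
    flags = (
        pd.DataFrame(flag_data, index=values.index, columns=sample_labels)
        if call_for_value
        else None
    )
    groups = {s: subsets[s] for s in sample_labels if s in subsets} or None
    if groups is not None and len(groups) != len(sample_labels):
        groups = None  # partial subset coverage: not a usable grouping
    return RawExpressionTable(
        values=values,
        flags=flags,
        probeset_to_gene=gene_map or None,
        replicate_groups=groups,
    )


def _call_to_record(call: PatternCall) -> dict:
    return {
        "gene_id": call.gene_id,
        "pattern_class": call.pattern_class,
        "dataset_id": call.dataset_id,
        "k": call.k,
        "samples": list(call.samples),
        "spm_values": list(call.spm_values),
        "scores": dict(call.scores),
    }


def _sorted_calls(calls: Iterable[PatternCall]) -> list[PatternCall]:
    order = {c: i for i, c in enumerate(CLASS_ORDER)}
    return sorted(calls, key=lambda c: (c.gene_id, order[c.pattern_class], c.k))


def write_report(calls: Iterable[PatternCall], path, format: str = "tsv") -> None:
    """Write pattern calls, sorted by (gene, class, k), as TSV or JSON.

    An empty call list yields a header-only TSV / empty JSON list.
    """
    path = Path(path)
    ordered = _sorted_calls(calls)
    if format == "json":
        path.write_text(json.dumps([_call_to_record(c) for c in ordered], indent=1) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for c in ordered:
            writer.writerow(
                [
                    c.gene_id,
                    c.pattern_class,
                    c.dataset_id,
                    c.k,
                    ";".join(c.samples),
                    ";".join(f"{v:.2f}" for v in c.spm_values),
                    f"{c.scores['DPM']:.2f}" if "DPM" in c.scores else "",
                    f"{c.scores['CTM']:.2f}" if "CTM" in c.scores else "",
                    f"{c.scores['RPM']:.2f}" if "RPM" in c.scores else "",
                ]
            )


def read_report(path, format: str = "tsv") -> list[PatternCall]:
    """Read a report back into pattern calls (JSON round-trips exactly;
    TSV at its 2-decimal display precision)."""
    path = Path(path)
    if format == "json":
        records = json.loads(path.read_text())
        return [
            PatternCall(
                gene_id=r["gene_id"],
                pattern_class=r["pattern_class"],
                samples=tuple(r["samples"]),
                spm_values=tuple(float(v) for v in r["spm_values"]),
                scores={k: float(v) for k, v in r["scores"].items()},
                k=int(r["k"]),
                dataset_id=r["dataset_id"],
            )
            for r in records
        ]
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    calls = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for r in reader:
            scores = {
                stat: float(r[stat]) for stat in ("DPM", "CTM", "RPM") if r.get(stat)
            }
            calls.append(
                PatternCall(
                    gene_id=r["gene_id"],
                    pattern_class=r["pattern_class"],
                    samples=tuple(r["samples"].split(";")),
                    spm_values=tuple(float(v) for v in r["spm_values"].split(";")),
                    scores=scores,
                    k=int(r["k"]),
                    dataset_id=r["dataset_id"],
                )
            )
    return calls


def read_thresholds(path) -> PatternThresholds:
    """Load classification thresholds from a YAML (or flat key: value) file."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return PatternThresholds()
    if not isinstance(data, dict):
        raise ProfileValidationError(f"{path}: expected a mapping of threshold names")
    return PatternThresholds.from_mapping(data)
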