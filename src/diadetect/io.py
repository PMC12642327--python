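"""Reading and q-value filtering of DIA-NN-style precursor reports.

A precursor report is a tab-separated table with one row per (run, precursor)
pair carrying the precursor quantity and three false-discovery q-values:
precursor-level (``Q.Value``), protein-group-level within run (``PG.Q.Value``)
and global protein-group level (``Global.Q.Value``). Identifications are
accepted when all three are at or below 1% FDR.

Internally both the report and the sample annotation are plain pandas
DataFrames with canonical column names (``REPORT_COLUMNS`` and
``ANNOTATION_COLUMNS``); the external column-name dialect is configurable
because DIA-NN headers drift between versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical internal column names of a precursor report
REPORT_COLUMNS = [
    "run_id",
    "protein_group",
    "gene",
    "precursor_id",
    "quantity",
    "q_precursor",
    "q_protein_group",
    "q_global",
]

#: canonical internal column names of a sample annotation table
ANNOTATION_COLUMNS = ["run_id", "group", "sex"]

#: default external header names, matching DIA-NN report conventions
DIANN_DIALECT: Mapping[str, str] = {
    "run_id": "Run",
    "protein_group": "Protein.Group",
    "gene": "Genes",
    "precursor_id": "Precursor.Id",
    "quantity": "Precursor.Quantity",
    "q_precursor": "Q.Value",
    "q_protein_group": "PG.Q.Value",
    "q_global": "Global.Q.Value",
}

GROUP_DEP = "Dep"
GROUP_NONDEP = "NonDep"

_NUMERIC_COLUMNS = ["quantity", "q_precursor", "q_protein_group", "q_global"]


class ReportFormatError(ValueError):
    """A report or annotation file violates its format contract."""


@dataclass(frozen=True)
class FilterThresholds:
    """Upper bounds on the three report q-values (inclusive comparison).

    The defaults implement the conventional 1% FDR acceptance on all three
    levels simultaneously.
    """

    max_q_precursor: float = 0.01
    max_q_protein_group: float = 0.01
    max_q_global: float = 0.01

    def __post_init__(self) -> None:
        for name in ("max_q_precursor", "max_q_protein_group", "max_q_global"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")


def read_report(
    path: str | Path,
    dialect: Mapping[str, str] = DIANN_DIALECT,
) -> pd.DataFrame:
    """Parse a tab-separated precursor report into canonical columns.

    Parameters
    ----------
    path
        Tab-separated file whose header contains every column named in
        ``dialect``.
    dialect
        Mapping from canonical names (:data:`REPORT_COLUMNS`) to the header
        names used in the file.

    Returns
    -------
    DataFrame with :data:`REPORT_COLUMNS`, one row per report row.

    Raises
    ------
    ReportFormatError
        If a mapped column is missing, a numeric field does not parse to a
        finite number, a quantity is negative, a q-value falls outside
        [0, 1], or a (run, precursor) pair occurs twice.
    """
    missing_keys = [k for k in REPORT_COLUMNS if k not in dialect]
    if missing_keys:
        raise ReportFormatError(f"dialect lacks canonical columns: {missing_keys}")

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [dialect[k] for k in REPORT_COLUMNS if dialect[k] not in raw.columns]
    if missing:
        raise ReportFormatError(f"report {path} is missing required column(s): {missing}")

    df = raw[[dialect[k] for k in REPORT_COLUMNS]].copy()
    df.columns = REPORT_COLUMNS

    for col in _NUMERIC_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(parsed.to_numpy(dtype=float))
        if bad.any():
            rows = df.index[bad][:5].tolist()
            raise ReportFormatError(
                f"column {dialect[col]!r} has non-finite or unparseable values "
                f"at data rows {rows} (showing at most 5)"
            )
        df[col] = parsed.astype(float)

    if (df["quantity"] < 0).any():
        raise ReportFormatError("negative precursor quantities are not allowed")
    for col in ("q_precursor", "q_protein_group", "q_global"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ReportFormatError(f"{col} values must lie in [0, 1]")

    dup = df.duplicated(subset=["run_id", "precursor_id"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["run_id", "precursor_id"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise ReportFormatError(
            f"duplicate (run, precursor) pairs: {sorted(offenders)[:10]}"
        )
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table (run_id, group, sex).

    Accepts tab- or comma-separated input with a header. ``group`` must be
    ``Dep`` or ``NonDep``; ``sex`` is free text (``F``/``M``/``unknown``
    conventional). A ``replicate_index`` column (1-based, per group) is added
    in file order if not present.
    """
    ann = pd.read_csv(path, sep=None, engine="python", dtype=str, encoding="utf-8")
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ReportFormatError(f"annotation {path} missing column(s): {missing}")
    return validate_annotations(ann)


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Check annotation invariants; return a copy with ``replicate_index``."""
    ann = ann.copy()
    if ann["run_id"].duplicated().any():
        raise ReportFormatError("annotation run_id values must be unique")
    bad_groups = set(ann["group"]) - {GROUP_DEP, GROUP_NONDEP}
    if bad_groups:
        raise ReportFormatError(
            f"unknown group labels {sorted(bad_groups)}; expected "
            f"{GROUP_DEP!r} or {GROUP_NONDEP!r}"
        )
    sizes = ann["group"].value_counts()
    small = sizes[sizes < 2]
    if not small.empty:
        raise ReportFormatError(f"each group needs >= 2 runs; got {sizes.to_dict()}")
    if "replicate_index" not in ann.columns:
        ann["replicate_index"] = ann.groupby("group").cumcount() + 1
    return ann


def apply_q_filters(
    report: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain rows passing all three q-value thresholds (inclusive ``<=``).

    Returns the filtered report (row order preserved) and a per-threshold
    rejection count. A row failing several thresholds is counted once under
    each. Idempotent and monotone in the thresholds.
    """
    masks = {
        "q_precursor": report["q_precursor"] <= thresholds.max_q_precursor,
        "q_protein_group": report["q_protein_group"] <= thresholds.max_q_protein_group,
        "q_global": report["q_global"] <= thresholds.max_q_global,
    }
    keep = masks["q_precursor"] & masks["q_protein_group"] & masks["q_global"]
    rejections = {name: int((~m).sum()) for name, m in masks.items()}
    for name, n_rej in rejections.items():
        logger.info("q-filter %s: rejected %d of %d rows", name, n_rej, len(report))
    return report.loc[keep].copy(), rejections


def count_summaries(
    report: pd.DataFrame,
    annotations: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run and per-group mean counts of distinct precursors and proteins.

    Every annotated run appears in the output, with zero counts if it has no
    report rows; a report run absent from the annotation is an error.

    Returns
    -------
    per_run : DataFrame indexed by run_id with columns
        ``group``, ``n_precursors``, ``n_protein_groups``.
    per_group : DataFrame indexed by group with columns
        ``mean_precursors``, ``mean_protein_groups``.
    """
    annotations = validate_annotations(annotations)
    known = set(annotations["run_id"])
    unknown = sorted(set(report["run_id"]) - known)
    if unknown:
        raise ReportFormatError(f"report runs without annotation: {unknown}")

    grouped = report.groupby("run_id").agg(
        n_precursors=("precursor_id", "nunique"),
        n_protein_groups=("protein_group", "nunique"),
    )
    per_run = (
        annotations.set_index("run_id")[["group"]]
        .join(grouped)
        .fillna(0)
        .astype({"n_precursors": int, "n_protein_groups": int})
    )
    per_group = per_run.groupby("group").agg(
        mean_precursors=("n_precursors", "mean"),
        mean_protein_groups=("n_protein_groups", "mean"),
    )
    return per_run, per_group


def write_report(report: pd.DataFrame, path: str | Path, dialect: Mapping[str, str] = DIANN_DIALECT) -> None:
    """Write a canonical report back out in the external TSV dialect."""
    out = report[REPORT_COLUMNS].copy()
    out.columns = [dialect[c] for c in REPORT_COLUMNS]
    out.to_csv(path, sep="\t", index=False)
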