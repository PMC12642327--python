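"""Per-group detection profiles and the group-unique/shared partition.

A protein's detection profile is the pair of counts (k_dep / n_dep,
k_non / n_non) of replicates per group in which it was quantified. A protein
counts as detected in a group when quantified in at least ``min_reps``
replicates of that group (default 2); proteins detected in exactly one group
are that group's "unique" set, detected in both are shared, and the remainder
are kept in an explicit fourth bucket for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GROUP_DEP, GROUP_NONDEP, validate_annotations

PROFILE_COLUMNS = ["protein_group", "gene", "k_dep", "n_dep", "k_non", "n_non"]


@dataclass(frozen=True)
class VennPartition:
    """Disjoint partition of profiled proteins by group detection."""

    dep_unique: frozenset[str]
    nondep_unique: frozenset[str]
    shared: frozenset[str]
    undetected_in_both: frozenset[str]

    def sizes(self) -> dict[str, int]:
        return {
            "dep_unique": len(self.dep_unique),
            "nondep_unique": len(self.nondep_unique),
            "shared": len(self.shared),
            "undetected_in_both": len(self.undetected_in_both),
        }


def detection_profiles(
    quant: pd.DataFrame,
    annotations: pd.DataFrame,
    genes: pd.Series | None = None,
) -> pd.DataFrame:
    """Count non-missing quant cells per group for every protein.

    Parameters
    ----------
    quant
        proteins x runs log2 quantity matrix (NaN = not quantified), as
        produced by :func:`diadetect.quant.quantify_all`.
    annotations
        Sample annotation covering every column of ``quant``.
    genes
        Optional protein_group -> gene symbol mapping; empty string when
        absent.

    Returns a DataFrame with :data:`PROFILE_COLUMNS`, one row per protein.
    """
    annotations = validate_annotations(annotations)
    ann = annotations.set_index("run_id")
    uncovered = [r for r in quant.columns if r not in ann.index]
    if uncovered:
        raise ValueError(f"runs without annotation: {uncovered}")

    dep_runs = [r for r in quant.columns if ann.loc[r, "group"] == GROUP_DEP]
    non_runs = [r for r in quant.columns if ann.loc[r, "group"] == GROUP_NONDEP]
    if not dep_runs or not non_runs:
        raise ValueError("both groups must have at least one run in the matrix")

    profiles = pd.DataFrame(
        {
            "protein_group": quant.index,
            "gene": (
                genes.reindex(quant.index).fillna("").to_numpy()
                if genes is not None
                else ""
            ),
            "k_dep": quant[dep_runs].notna().sum(axis=1).to_numpy(),
            "n_dep": len(dep_runs),
            "k_non": quant[non_runs].notna().sum(axis=1).to_numpy(),
            "n_non": len(non_runs),
        }
    ).reset_index(drop=True)
    return profiles


def group_detected(profile, min_reps: int = 2) -> tuple[bool, bool]:
    """Apply the >= min_reps detection rule to one profile row."""
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    return bool(profile.k_dep >= min_reps), bool(profile.k_non >= min_reps)


def venn_partition(profiles: pd.DataFrame, min_reps: int = 2) -> VennPartition:
    """Partition proteins into Dep-unique / Non-dep-unique / shared / neither."""
    if profiles.empty:
        raise ValueError("no profiles to partition")
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    in_dep = profiles["k_dep"] >= min_reps
    in_non = profiles["k_non"] >= min_reps
    pg = profiles["protein_group"]
    return VennPartition(
        dep_unique=frozenset(pg[in_dep & ~in_non]),
        nondep_unique=frozenset(pg[~in_dep & in_non]),
        shared=frozenset(pg[in_dep & in_non]),
        undetected_in_both=frozenset(pg[~in_dep & ~in_non]),
    )


def detection_heatmap_table(
    profiles: pd.DataFrame,
    quant: pd.DataFrame,
    top_k: int,
    require_opposite_zero: bool = False,
) -> pd.DataFrame:
    """Binary detection table of the ``top_k`` most group-specific proteins.

    Proteins are ranked by the absolute difference of per-group detection
    proportions |k_dep/n_dep - k_non/n_non| (descending), ties broken by
    protein_group lexicographic order. With ``require_opposite_zero``, only
    proteins detected in >= 2 replicates of one group and 0 of the other are
    eligible — the stricter selection used for group-specificity displays.

    Returns a 0/1 DataFrame (protein x run) in ranked order.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    p = profiles.copy()
    p["specificity"] = np.abs(p["k_dep"] / p["n_dep"] - p["k_non"] / p["n_non"])
    if require_opposite_zero:
        eligible = ((p["k_dep"] >= 2) & (p["k_non"] == 0)) | (
            (p["k_non"] >= 2) & (p["k_dep"] == 0)
        )
        p = p[eligible]
    p = p.sort_values(
        ["specificity", "protein_group"], ascending=[False, True], kind="mergesort"
    )
    chosen = p["protein_group"].head(top_k)
    return quant.loc[chosen].notna().astype(int)


def profiles_table(profiles: pd.DataFrame, min_reps: int = 2) -> pd.DataFrame:
    """Profiles with detected_dep / detected_non flags, ready for TSV export."""
    out = profiles.copy()
    out["detected_dep"] = out["k_dep"] >= min_reps
    out["detected_non"] = out["k_non"] >= min_reps
    return out
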