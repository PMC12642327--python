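"""Evidence-tier classification of group-preferred detection profiles.

Each profile receives exactly one label, evaluated in strict precedence:

1. ``strong_dep``     — detected in >= 75% of Dep runs and <= 20% of Non-dep
2. ``strong_nondep``  — detected in >= 80% of Non-dep runs and <= 25% of Dep
3. ``moderate_dep``   — >= 50% of Dep runs with clear preference
4. ``moderate_nondep``— >= 60% of Non-dep runs with clear preference
5. ``shared``         — detected (>= 2 replicates) in both groups
6. ``weak``           — everything else (below 50% of the preferred group, or
   substantial detection in both groups without a clear preference)

"Clear preference" is operationalized as: the comparison group is detected in
at most ``other_max_count`` replicates (default 1) and the preferred group's
detection proportion is strictly greater. The asymmetric strong-tier defaults
(0.75/0.20 vs 0.80/0.25) arise from group sizes of 4 and 5; expressed as
proportions they generalize to other designs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd


class EvidenceLabel(str, enum.Enum):
    STRONG_DEP = "strong_dep"
    MODERATE_DEP = "moderate_dep"
    STRONG_NONDEP = "strong_nondep"
    MODERATE_NONDEP = "moderate_nondep"
    SHARED = "shared"
    WEAK = "weak"

    @property
    def strength_text(self) -> str:
        """Human-readable evidence-strength wording for table export."""
        return {
            EvidenceLabel.STRONG_DEP: "Strong",
            EvidenceLabel.STRONG_NONDEP: "Strong",
            EvidenceLabel.MODERATE_DEP: "Moderate",
            EvidenceLabel.MODERATE_NONDEP: "Moderate",
            EvidenceLabel.SHARED: "Shared",
            EvidenceLabel.WEAK: "Weak",
        }[self]


@dataclass(frozen=True)
class ClassifierThresholds:
    """Detection-proportion thresholds of the evidence tiers."""

    strong_dep_min_prop: float = 0.75
    strong_dep_other_max_prop: float = 0.20
    strong_nondep_min_prop: float = 0.80
    strong_nondep_other_max_prop: float = 0.25
    moderate_dep_min_prop: float = 0.50
    moderate_nondep_min_prop: float = 0.60
    clear_pref_other_max_count: int = 1
    shared_min_reps: int = 2

    def __post_init__(self) -> None:
        for pref, strong, other in (
            ("dep", self.strong_dep_min_prop, self.strong_dep_other_max_prop),
            ("nondep", self.strong_nondep_min_prop, self.strong_nondep_other_max_prop),
        ):
            moderate = getattr(self, f"moderate_{pref}_min_prop")
            if not 0 < moderate <= strong <= 1:
                raise ValueError(
                    f"need 0 < moderate <= strong <= 1 for {pref}; "
                    f"got moderate={moderate}, strong={strong}"
                )
            if not 0 <= other < moderate:
                raise ValueError(
                    f"need 0 <= strong-other-max < moderate for {pref}; "
                    f"got other={other}, moderate={moderate}"
                )
        if self.clear_pref_other_max_count < 0 or self.shared_min_reps < 1:
            raise ValueError("count thresholds out of range")


def classify(
    k_dep: int,
    n_dep: int,
    k_non: int,
    n_non: int,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> EvidenceLabel:
    """Assign the evidence label for one detection profile."""
    if not (0 <= k_dep <= n_dep and 0 <= k_non <= n_non):
        raise ValueError(f"invalid profile ({k_dep}/{n_dep}, {k_non}/{n_non})")
    t = thresholds
    p_dep, p_non = k_dep / n_dep, k_non / n_non

    if p_dep >= t.strong_dep_min_prop and p_non <= t.strong_dep_other_max_prop:
        return EvidenceLabel.STRONG_DEP
    if p_non >= t.strong_nondep_min_prop and p_dep <= t.strong_nondep_other_max_prop:
        return EvidenceLabel.STRONG_NONDEP
    if (
        p_dep >= t.moderate_dep_min_prop
        and k_non <= t.clear_pref_other_max_count
        and p_dep > p_non
    ):
        return EvidenceLabel.MODERATE_DEP
    if (
        p_non >= t.moderate_nondep_min_prop
        and k_dep <= t.clear_pref_other_max_count
        and p_non > p_dep
    ):
        return EvidenceLabel.MODERATE_NONDEP
    if k_dep >= t.shared_min_reps and k_non >= t.shared_min_reps:
        return EvidenceLabel.SHARED
    return EvidenceLabel.WEAK


def classify_all(
    profiles: pd.DataFrame,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every profile row; return the table and per-label counts.

    The returned table mirrors the layout of a published evidence table:
    protein, gene, per-group detection fractions, machine label and
    evidence-strength text.
    """
    labels = [
        classify(r.k_dep, r.n_dep, r.k_non, r.n_non, thresholds)
        for r in profiles.itertuples(index=False)
    ]
    out = profiles.copy()
    out["label"] = [lab.value for lab in labels]
    out["evidence_strength"] = [lab.strength_text for lab in labels]
    out["dep_detection"] = [
        f"{r.k_dep}/{r.n_dep} ({r.k_dep / r.n_dep:.0%})"
        for r in profiles.itertuples(index=False)
    ]
    out["nondep_detection"] = [
        f"{r.k_non}/{r.n_non} ({r.k_non / r.n_non:.0%})"
        for r in profiles.itertuples(index=False)
    ]
    counts = {lab.value: 0 for lab in EvidenceLabel}
    for lab in labels:
        counts[lab.value] += 1
    return out, counts
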