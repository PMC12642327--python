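"""Synthetic DIA-style reports with planted group structure and MNAR censoring.

The generator emulates the structure that makes presence/absence analysis of
DIA data informative: detection failures are driven by abundance relative to
a limit of detection (missing not at random), proteins carry several
precursors, and the report's q-value columns contain a small fraction of
above-threshold decoy rows so the filtering stage has something to reject.

Two generation modes are supported per protein:

* abundance mode — a run-level protein log2 abundance is drawn around the
  group mean, each precursor adds a fixed offset plus measurement noise, and
  a precursor row is emitted only if its log2 intensity clears the detection
  limit. This produces genuinely MNAR missingness.
* probability mode — each protein x run is detected independently with the
  group's stated probability and intensities are drawn above the limit.
  This gives closed-form binomial expectations for validating the
  classifier and power machinery.

Every draw descends from a single ``numpy.random.default_rng`` seed, so a
fixture is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GROUP_DEP, GROUP_NONDEP, REPORT_COLUMNS

#: standard deviation of per-cell measurement noise (log2 units)
MEASUREMENT_SD = 0.2


@dataclass(frozen=True)
class ProteinSpec:
    """One planted protein: either abundance means or detection probabilities.

    Exactly one of (mean_log2_dep, mean_log2_non) / (p_dep, p_non) must be
    set; the former selects abundance mode, the latter probability mode.
    """

    protein_id: str
    gene: str = ""
    n_precursors: int = 2
    mean_log2_dep: float | None = None
    mean_log2_non: float | None = None
    p_dep: float | None = None
    p_non: float | None = None

    def __post_init__(self) -> None:
        abundance = self.mean_log2_dep is not None and self.mean_log2_non is not None
        prob = self.p_dep is not None and self.p_non is not None
        if abundance == prob:
            raise ValueError(
                f"{self.protein_id}: set either abundance means or detection "
                "probabilities, not both"
            )
        if prob and not (0 <= self.p_dep <= 1 and 0 <= self.p_non <= 1):
            raise ValueError(f"{self.protein_id}: probabilities must lie in [0, 1]")
        if self.n_precursors < 1:
            raise ValueError(f"{self.protein_id}: need >= 1 precursor")

    @property
    def mode(self) -> str:
        return "abundance" if self.mean_log2_dep is not None else "probability"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped simulation settings.

    Defaults mirror a two-group design of 4 dependent vs 5 non-dependent
    runs with moderate replicate variation (0.5 log2 units), precursor
    ionization offsets of 1 log2 unit, and 2% spurious above-threshold rows.
    """

    proteins: Sequence[ProteinSpec]
    n_dep: int = 4
    n_non: int = 5
    replicate_sd: float = 0.5
    precursor_offset_sd: float = 1.0
    lod_log2: float = 10.0
    q_spurious_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dep < 2 or self.n_non < 2:
            raise ValueError("group sizes must be >= 2")
        if self.replicate_sd < 0 or self.precursor_offset_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.q_spurious_fraction < 1:
            raise ValueError("q_spurious_fraction must lie in [0, 1)")
        if not self.proteins:
            raise ValueError("at least one protein spec required")


def annotations_for(config: SyntheticConfig) -> pd.DataFrame:
    """Sample annotation matching the generated report (sex alternates F/M)."""
    rows = []
    for grp, n in ((GROUP_DEP, config.n_dep), (GROUP_NONDEP, config.n_non)):
        for i in range(1, n + 1):
            rows.append(
                {
                    "run_id": f"{grp}_{i}",
                    "group": grp,
                    "sex": "F" if i % 2 else "M",
                    "replicate_index": i,
                }
            )
    return pd.DataFrame(rows)


def _planted_class(p_dep: float, p_non: float) -> str:
    if p_dep >= 0.5 and p_non < 0.5:
        return "dep_preferred"
    if p_non >= 0.5 and p_dep < 0.5:
        return "nondep_preferred"
    if p_dep >= 0.5 and p_non >= 0.5:
        return "shared"
    return "absent"


def _implied_detection_prob(
    spec: ProteinSpec, group_mean: float, config: SyntheticConfig, rng: np.random.Generator
) -> float:
    # Monte-Carlo estimate of P(>=1 precursor above LOD in a run) under the
    # abundance model; only used to annotate the truth table.
    n = 4000
    z = rng.normal(0.0, config.replicate_sd, size=n)
    offsets = rng.normal(0.0, config.precursor_offset_sd, size=(n, spec.n_precursors))
    noise = rng.normal(0.0, MEASUREMENT_SD, size=(n, spec.n_precursors))
    intensity = group_mean + z[:, None] + offsets + noise
    return float((intensity >= config.lod_log2).any(axis=1).mean())


def generate_report(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a precursor report and its ground-truth table.

    Returns
    -------
    report : DataFrame with the canonical report columns, one row per emitted
        (run, precursor) observation, including the spurious decoy rows.
    truth : DataFrame with one row per planted protein: ``protein_id``,
        ``gene``, ``mode``, ``planted_class`` and the true (probability mode)
        or implied (abundance mode) per-group detection probabilities.
    """
    rng = np.random.default_rng(config.seed)
    ann = annotations_for(config)
    runs = list(ann["run_id"])
    groups = dict(zip(ann["run_id"], ann["group"]))

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for spec in config.proteins:
        offsets = rng.normal(0.0, config.precursor_offset_sd, size=spec.n_precursors)
        if spec.mode == "abundance":
            p_dep = _implied_detection_prob(spec, spec.mean_log2_dep, config, rng)
            p_non = _implied_detection_prob(spec, spec.mean_log2_non, config, rng)
        else:
            p_dep, p_non = float(spec.p_dep), float(spec.p_non)
        truth_rows.append(
            {
                "protein_id": spec.protein_id,
                "gene": spec.gene,
                "mode": spec.mode,
                "planted_class": _planted_class(p_dep, p_non),
                "p_dep": p_dep,
                "p_non": p_non,
            }
        )
        for run in runs:
            is_dep = groups[run] == GROUP_DEP
            if spec.mode == "abundance":
                mean = spec.mean_log2_dep if is_dep else spec.mean_log2_non
                protein_level = mean + rng.normal(0.0, config.replicate_sd)
                intensities = (
                    protein_level
                    + offsets
                    + rng.normal(0.0, MEASUREMENT_SD, size=spec.n_precursors)
                )
                emit = intensities >= config.lod_log2  # MNAR censoring
            else:
                detected = rng.random() < (p_dep if is_dep else p_non)
                # detected proteins get all precursors above the limit
                intensities = (
                    config.lod_log2
                    + 2.0
                    + np.abs(offsets)
                    + np.abs(rng.normal(0.0, MEASUREMENT_SD, size=spec.n_precursors))
                )
                emit = np.full(spec.n_precursors, detected)
            for j in np.flatnonzero(emit):
                rows.append(
                    {
                        "run_id": run,
                        "protein_group": spec.protein_id,
                        "gene": spec.gene,
                        "precursor_id": f"{spec.protein_id}_PEP{j + 1}.2",
                        "quantity": float(2.0 ** intensities[j]),
                        "q_precursor": float(rng.uniform(0.0, 0.01)),
                        "q_protein_group": float(rng.uniform(0.0, 0.01)),
                        "q_global": float(rng.uniform(0.0, 0.01)),
                    }
                )

    n_spurious = int(round(config.q_spurious_fraction * len(rows)))
    for s in range(n_spurious):
        spec = config.proteins[int(rng.integers(len(config.proteins)))]
        run = runs[int(rng.integers(len(runs)))]
        rows.append(
            {
                "run_id": run,
                "protein_group": f"DECOY-{spec.protein_id}",
                "gene": "",
                "precursor_id": f"DECOY-{spec.protein_id}_S{s}.2",
                "quantity": float(2.0 ** rng.uniform(config.lod_log2, config.lod_log2 + 4)),
                "q_precursor": float(rng.uniform(0.0, 0.01)),
                "q_protein_group": float(rng.uniform(0.0, 0.01)),
                "q_global": float(rng.uniform(0.011, 0.05)),
            }
        )

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return report, truth


def make_study_like_fixture(
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """A study-shaped fixture: 611 proteins planted as 140/67/404.

    140 proteins are dependent-preferred (detection probability 0.9–1.0 in
    the dependent group, 0–0.2 in the other), 67 are non-dependent-preferred
    (mirrored), and 404 are shared at high probability in both groups, over
    4 vs 5 runs. Returns (report, truth, annotations).
    """
    rng = np.random.default_rng(seed)
    specs: list[ProteinSpec] = []

    def add(prefix: str, count: int, lo_dep, hi_dep, lo_non, hi_non) -> None:
        for i in range(count):
            specs.append(
                ProteinSpec(
                    protein_id=f"{prefix}{i + 1:04d}",
                    gene=f"{prefix}{i + 1:04d}_G",
                    n_precursors=int(rng.integers(1, 5)),
                    p_dep=float(rng.uniform(lo_dep, hi_dep)),
                    p_non=float(rng.uniform(lo_non, hi_non)),
                )
            )

    add("DEPP", 140, 0.9, 1.0, 0.0, 0.2)
    add("NONP", 67, 0.0, 0.2, 0.9, 1.0)
    add("SHRD", 404, 0.9, 1.0, 0.9, 1.0)
    config = SyntheticConfig(proteins=tuple(specs), seed=int(rng.integers(2**31)))
    report, truth = generate_report(config)
    return report, truth, annotations_for(config)
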