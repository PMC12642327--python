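"""End-to-end orchestration: ingest -> quantify -> detect -> classify -> ORA.

``run_pipeline`` wires the stages together, writes each stage's output as
TSV/JSON next to a manifest of row counts and the resolved parameters, and is
deterministic given its inputs. ``pca_coordinates`` provides the
quality-control projection of runs: either on proteins quantified in every
run (complete-case log2 quantities, no imputation — imputing an MNAR matrix
would inject group structure) or on the 0/1 detection matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import enrich, io, quant
from .classify import ClassifierThresholds, classify_all
from .detection import (
    detection_heatmap_table,
    detection_profiles,
    profiles_table,
    venn_partition,
)
from .io import FilterThresholds

logger = logging.getLogger(__name__)

PcaMode = Literal["complete_proteins_log2", "binary_detection"]


@dataclass(frozen=True)
class PipelineConfig:
    report_path: str
    annotation_path: str
    output_dir: str
    thresholds: FilterThresholds = FilterThresholds()
    min_reps: int = 2
    classifier: ClassifierThresholds = ClassifierThresholds()
    gmt_paths: tuple[str, ...] = ()
    background: Literal["detected_either", "custom_list"] = "detected_either"
    custom_background: tuple[str, ...] = ()
    pca_input: PcaMode = "complete_proteins_log2"
    heatmap_top_k: int = 10


def pca_coordinates(
    quant_matrix: pd.DataFrame,
    mode: PcaMode = "complete_proteins_log2",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project runs onto the top two principal axes.

    Parameters
    ----------
    quant_matrix
        proteins x runs log2 quantity matrix with NaN for missing cells.
    mode
        ``complete_proteins_log2`` uses only proteins quantified in every
        run; ``binary_detection`` uses the 0/1 detection matrix.

    Returns
    -------
    coords : runs x 2 DataFrame (columns PC1, PC2).
    explained : explained-variance fractions of all principal axes
        (non-negative, summing to 1 for a non-degenerate matrix).

    The sign of each axis is fixed so its first nonzero loading is positive.
    """
    if quant_matrix.shape[1] < 3:
        raise ValueError("PCA needs >= 3 runs")
    if mode == "complete_proteins_log2":
        complete = quant_matrix.dropna(axis=0)
        if complete.shape[0] < 2:
            raise ValueError(
                "fewer than 2 proteins quantified in all runs; "
                "use binary_detection mode instead"
            )
        data = complete.to_numpy(dtype=float)
    elif mode == "binary_detection":
        data = quant_matrix.notna().to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown PCA mode {mode!r}")

    x = data.T  # runs x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix sign per axis: first nonzero loading positive
    for a in range(vt.shape[0]):
        nz = np.flatnonzero(np.abs(vt[a]) > 1e-12)
        if nz.size and vt[a, nz[0]] < 0:
            vt[a] *= -1.0
            u[:, a] *= -1.0
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    scores = u * s
    coords = pd.DataFrame(
        scores[:, :2], index=quant_matrix.columns, columns=["PC1", "PC2"]
    )
    coords.index.name = "run_id"
    return coords, explained


def confidence_ellipses(
    coords: pd.DataFrame, annotations: pd.DataFrame, level: float = 0.95
) -> dict[str, dict]:
    """Per-group 95% confidence ellipse parameters in PC1/PC2 space.

    Returns, per group, the center, semi-axis lengths and rotation angle
    (radians) of the chi-square confidence ellipse of the group mean cloud.
    """
    from scipy import stats

    ann = annotations.set_index("run_id")
    out: dict[str, dict] = {}
    q = stats.chi2.ppf(level, df=2)
    for grp, sub in coords.groupby(ann.loc[coords.index, "group"]):
        xy = sub.to_numpy()
        center = xy.mean(axis=0)
        if len(sub) < 3:
            out[grp] = {"center": center.tolist(), "semi_axes": None, "angle": None}
            continue
        cov = np.cov(xy, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        out[grp] = {
            "center": center.tolist(),
            "semi_axes": list(np.sqrt(np.maximum(evals, 0) * q)),
            "angle": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle.

    Writes, under ``config.output_dir``: the filtered report, the protein
    quantity matrix, detection profiles, evidence labels, Venn counts,
    heatmap table, PCA coordinates and ellipses, ORA tables (one per GMT),
    and ``manifest.json`` echoing parameters and row counts. Returns the
    manifest dict.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "thresholds": vars(config.thresholds).copy(),
            "min_reps": config.min_reps,
            "classifier": vars(config.classifier).copy(),
            "background": config.background,
            "pca_input": config.pca_input,
        },
        "stages": {},
    }

    report = io.read_report(config.report_path)
    ann = io.read_annotations(config.annotation_path)
    filtered, rejections = io.apply_q_filters(report, config.thresholds)
    io.write_report(filtered, outdir / "filtered_report.tsv")
    manifest["stages"]["ingest"] = {
        "rows_in": len(report),
        "rows_filtered": len(filtered),
        "rejections": rejections,
    }
    per_run, per_group = io.count_summaries(filtered, ann)
    per_run.to_csv(outdir / "counts_per_run.tsv", sep="\t")
    per_group.to_csv(outdir / "counts_per_group.tsv", sep="\t")

    if filtered.empty:
        logger.warning("no rows pass the q-value filters; downstream tables empty")
        manifest["stages"]["empty"] = True
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    qmat = quant.quantify_all(filtered, ann)
    quant.write_quant_matrix(qmat, outdir / "protein_quant.tsv")
    manifest["stages"]["quant"] = {"n_proteins": qmat.shape[0], "n_runs": qmat.shape[1]}

    genes = (
        filtered.drop_duplicates("protein_group")
        .set_index("protein_group")["gene"]
    )
    profiles = detection_profiles(qmat, ann, genes=genes)
    profiles_table(profiles, config.min_reps).to_csv(
        outdir / "detection_profiles.tsv", sep="\t", index=False
    )
    venn = venn_partition(profiles, config.min_reps)
    (outdir / "venn.json").write_text(json.dumps(venn.sizes(), indent=2))
    manifest["stages"]["detection"] = venn.sizes()

    heat = detection_heatmap_table(profiles, qmat, config.heatmap_top_k)
    heat.to_csv(outdir / "heatmap_table.tsv", sep="\t")

    labeled, label_counts = classify_all(profiles, config.classifier)
    labeled.to_csv(outdir / "evidence_labels.tsv", sep="\t", index=False)
    manifest["stages"]["classification"] = label_counts

    try:
        coords, explained = pca_coordinates(qmat, config.pca_input)
    except ValueError:
        if config.pca_input == "complete_proteins_log2":
            logger.warning("falling back to binary-detection PCA")
            coords, explained = pca_coordinates(qmat, "binary_detection")
        else:
            raise
    pca_out = coords.copy()
    pca_out.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
    ell = confidence_ellipses(coords, ann)
    (outdir / "pca_ellipses.json").write_text(json.dumps(ell, indent=2))
    manifest["stages"]["pca"] = {"explained_variance": explained[:2].tolist()}

    if config.gmt_paths:
        if config.background == "detected_either":
            detected = profiles[
                (profiles["k_dep"] >= config.min_reps)
                | (profiles["k_non"] >= config.min_reps)
            ]
            background = set(detected.loc[detected["gene"] != "", "gene"])
        else:
            background = set(config.custom_background)
        manifest["stages"]["ora"] = {}
        for side, labels in (
            ("dep", {"strong_dep", "moderate_dep"}),
            ("nondep", {"strong_nondep", "moderate_nondep"}),
        ):
            query = enrich.query_from_labels(labeled, labels) & background
            if not query:
                continue
            for gmt_path in config.gmt_paths:
                coll = enrich.read_gmt(gmt_path)
                res = enrich.ora(query, coll, background)
                name = f"ora_{side}_{Path(gmt_path).stem}.tsv"
                res.to_csv(outdir / name, sep="\t", index=False)
                manifest["stages"]["ora"][name] = len(res)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
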