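"""MaxLFQ-style aggregation of precursor intensities to protein quantities.

The estimator works on log2 intensities. For each pair of runs sharing at
least ``min_shared`` precursors of a protein, the protein-level log2 ratio
between the runs is estimated as the median over shared precursors of the
per-precursor intensity difference. Run-level log2 protein quantities x are
then the least-squares solution of

    minimize  sum over pairs (i, j)  (x_i - x_j - r_ij)^2

which determines x up to an additive constant per connected component of the
run-sharing graph. Each component is anchored so that the mean of x over its
runs equals the mean of the per-run mean observed precursor log2 intensity —
this keeps the output on the scale of the input intensities and makes the
one-precursor case an exact identity. Runs in which no precursor of the
protein was quantified stay missing (NaN).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .io import REPORT_COLUMNS


def maxlfq(values: np.ndarray, min_shared: int = 1) -> np.ndarray:
    """Estimate per-run log2 protein quantities from a peptide matrix.

    Parameters
    ----------
    values
        precursors x runs array of log2 intensities, NaN marking precursors
        not quantified in a run. Must contain at least one finite value.
    min_shared
        Minimum number of precursors two runs must share for their pairwise
        ratio to enter the fit (default 1).

    Returns
    -------
    Length-``n_runs`` array of log2 protein quantities; NaN for runs with no
    observed precursor.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("peptide matrix must be a non-empty 2-D array")
    observed = np.isfinite(values)
    if not observed.any():
        raise ValueError("peptide matrix has no observed value")

    n_runs = values.shape[1]
    run_has_data = observed.any(axis=0)
    # median pairwise log-ratios over shared precursors
    adj = np.zeros((n_runs, n_runs), dtype=bool)
    ratios: dict[tuple[int, int], float] = {}
    for i, j in combinations(np.flatnonzero(run_has_data), 2):
        shared = observed[:, i] & observed[:, j]
        if shared.sum() >= max(min_shared, 1):
            ratios[(i, j)] = float(np.median(values[shared, i] - values[shared, j]))
            adj[i, j] = adj[j, i] = True

    x = np.full(n_runs, np.nan)
    n_comp, labels = connected_components(adj, directed=False)
    masked = np.where(observed, values, 0.0)
    counts = observed.sum(axis=0)
    per_run_mean = np.divide(
        masked.sum(axis=0), counts, out=np.full(n_runs, np.nan), where=counts > 0
    )

    for comp in range(n_comp):
        members = np.flatnonzero((labels == comp) & run_has_data)
        if members.size == 0:
            continue
        anchor = float(np.mean(per_run_mean[members]))
        if members.size == 1:
            x[members[0]] = anchor
            continue
        # normal equations of the pairwise least-squares problem (graph
        # Laplacian); singular only along the constant vector, removed by the
        # mean-anchoring constraint
        pos = {run: idx for idx, run in enumerate(members)}
        m = members.size
        lap = np.zeros((m, m))
        rhs = np.zeros(m)
        for (i, j), r in ratios.items():
            if labels[i] != comp:
                continue
            a, b = pos[i], pos[j]
            lap[a, a] += 1.0
            lap[b, b] += 1.0
            lap[a, b] -= 1.0
            lap[b, a] -= 1.0
            rhs[a] += r
            rhs[b] -= r
        sol, *_ = np.linalg.lstsq(lap, rhs, rcond=None)
        sol += anchor - sol.mean()
        x[members] = sol
    return x


def quantify_all(
    report: pd.DataFrame,
    annotations: pd.DataFrame,
    min_shared: int = 1,
) -> pd.DataFrame:
    """Build the proteins x runs log2 quantity matrix from a filtered report.

    Rows with zero quantity are treated as not quantified (detection equals
    quantification); all other quantities enter as log2. A cell is non-missing
    iff at least one precursor of the protein was quantified in that run.

    Returns a DataFrame indexed by protein_group with one column per
    annotated run (annotation order), NaN marking missing cells.
    """
    missing_cols = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing_cols:
        raise ValueError(f"report lacks canonical columns: {missing_cols}")
    runs = list(annotations["run_id"])
    proteins = sorted(report["protein_group"].unique())
    out = pd.DataFrame(np.nan, index=pd.Index(proteins, name="protein_group"), columns=runs)

    quantified = report[report["quantity"] > 0]
    run_pos = {r: i for i, r in enumerate(runs)}
    for protein, sub in quantified.groupby("protein_group"):
        precursors = sorted(sub["precursor_id"].unique())
        prec_pos = {p: i for i, p in enumerate(precursors)}
        mat = np.full((len(precursors), len(runs)), np.nan)
        for row in sub.itertuples(index=False):
            mat[prec_pos[row.precursor_id], run_pos[row.run_id]] = np.log2(row.quantity)
        out.loc[protein] = maxlfq(mat, min_shared=min_shared)
    return out


def write_quant_matrix(matrix: pd.DataFrame, path) -> None:
    """Write the protein x run matrix as TSV with missing cells as ``NA``."""
    matrix.to_csv(path, sep="\t", na_rep="NA")
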