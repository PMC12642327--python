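import numpy as np
import pandas as pd
import pytest

from diadetect.quant import maxlfq, quantify_all

from conftest import make_report_df

NAN = np.nan


def brute_force_maxlfq(values: np.ndarray, min_shared: int = 1) -> np.ndarray:
    """Independent oracle: constrained least squares via the KKT system.

    Recomputes the pairwise median log-ratios from scratch, stacks one
    residual row per run pair, and solves min ||Ax - r|| subject to
    mean(x) = anchor with a Lagrange multiplier, per connected component.
    """
    values = np.asarray(values, float)
    obs = np.isfinite(values)
    n = values.shape[1]
    has = obs.any(axis=0)
    pairs, r = [], []
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[:, i] & obs[:, j]
            if shared.sum() >= min_shared:
                pairs.append((i, j))
                r.append(np.median(values[shared, i] - values[shared, j]))
    # connected components by simple flood fill
    comp = -np.ones(n, int)
    c = 0
    for start in range(n):
        if not has[start] or comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = c
        while stack:
            u = stack.pop()
            for (i, j) in pairs:
                for a, b in ((i, j), (j, i)):
                    if a == u and comp[b] < 0:
                        comp[b] = c
                        stack.append(b)
        c += 1
    x = np.full(n, np.nan)
    for cc in range(c):
        members = np.flatnonzero(comp == cc)
        run_means = [values[obs[:, m], m].mean() for m in members]
        anchor = float(np.mean(run_means))
        m = len(members)
        pos = {run: k for k, run in enumerate(members)}
        rows = [(pos[i], pos[j], rij) for (i, j), rij in zip(pairs, r) if comp[i] == cc]
        if not rows:
            x[members] = anchor
            continue
        A = np.zeros((len(rows), m))
        rhs = np.array([rij for _, _, rij in rows])
        for k, (a, b, _) in enumerate(rows):
            A[k, a], A[k, b] = 1.0, -1.0
        kkt = np.zeros((m + 1, m + 1))
        kkt[:m, :m] = A.T @ A
        kkt[:m, m] = 1.0
        kkt[m, :m] = 1.0
        sol = np.linalg.solve(kkt, np.concatenate([A.T @ rhs, [m * anchor]]))
        x[members] = sol[:m]
    return x


class TestMaxlfq:
    def test_single_precursor_identity(self):
        est = maxlfq(np.array([[10.0, 11.0, NAN]]))
        np.testing.assert_allclose(est[:2], [10.0, 11.0])
        assert np.isnan(est[2])

    def test_consistent_ratios_preserved_exactly(self):
        est = maxlfq(np.array([[10.0, 12.0], [8.0, 10.0]]))
        assert est[1] - est[0] == pytest.approx(2.0)
        # anchor: mean of per-run mean observed intensities = (9 + 11) / 2
        assert est.mean() == pytest.approx(10.0)

    def test_conflicting_ratios_median_and_oracle(self):
        # run differences 2 and 4 -> median 3; levels fixed by the anchor
        mat = np.array([[10.0, 12.0], [10.0, 14.0]])
        est = maxlfq(mat)
        assert est[1] - est[0] == pytest.approx(3.0)
        np.testing.assert_allclose(est, brute_force_maxlfq(mat), atol=1e-9)

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_brute_force_on_random_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_prec = rng.integers(1, 6)
        n_runs = rng.integers(2, 6)
        mat = rng.normal(12, 2, size=(n_prec, n_runs))
        mat[rng.random(mat.shape) < 0.3] = NAN
        if not np.isfinite(mat).any():
            mat[0, 0] = 12.0
        np.testing.assert_allclose(
            maxlfq(mat), brute_force_maxlfq(mat), atol=1e-9, equal_nan=True
        )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(12, 2, size=(4, 5))
        mat[rng.random(mat.shape) < 0.2] = NAN
        shift = np.log2(4.0)
        np.testing.assert_allclose(maxlfq(mat + shift), maxlfq(mat) + shift, atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        mat = rng.normal(10, 1, size=(3, 4))
        base = maxlfq(mat)
        perm_prec = rng.permutation(3)
        np.testing.assert_allclose(maxlfq(mat[perm_prec]), base, atol=1e-12)
        perm_runs = rng.permutation(4)
        np.testing.assert_allclose(maxlfq(mat[:, perm_runs]), base[perm_runs], atol=1e-12)

    def test_disconnected_components_anchored_independently(self):
        # precursor 1 covers runs 0-1, precursor 2 covers runs 2-3: no shared run
        mat = np.array([[10.0, 11.0, NAN, NAN], [NAN, NAN, 20.0, 22.0]])
        est = maxlfq(mat)
        np.testing.assert_allclose(est, [10.0, 11.0, 20.0, 22.0])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            maxlfq(np.full((2, 2), NAN))


class TestQuantifyAll:
    def _report(self):
        rows = []
        for run, qty in [("Dep_1", 1024.0), ("Dep_2", 2048.0)]:
            rows.append((run, "P1", "G1", "P1_PEP1.2", qty, 0.0, 0.0, 0.0))
        rows.append(("NonDep_1", "P2", "G2", "P2_PEP1.2", 4096.0, 0.0, 0.0, 0.0))
        return make_report_df(rows)

    def test_structure_and_missingness(self, annotations_4v5):
        mat = quantify_all(self._report(), annotations_4v5)
        assert mat.shape == (2, 9)
        assert mat.loc["P1", "Dep_1"] == pytest.approx(10.0)
        assert mat.loc["P1", "Dep_2"] == pytest.approx(11.0)
        assert mat.loc["P2", "NonDep_1"] == pytest.approx(12.0)
        assert mat.loc["P1"].notna().sum() == 2
        assert mat.loc["P2"].notna().sum() == 1

    def test_zero_quantity_is_not_quantified(self, annotations_4v5):
        rows = [
            ("Dep_1", "P1", "G1", "P1_PEP1.2", 0.0, 0.0, 0.0, 0.0),
            ("Dep_2", "P1", "G1", "P1_PEP1.2", 1024.0, 0.0, 0.0, 0.0),
        ]
        mat = quantify_all(make_report_df(rows), annotations_4v5)
        assert np.isnan(mat.loc["P1", "Dep_1"])
        assert mat.loc["P1", "Dep_2"] == pytest.approx(10.0)

    def test_global_intensity_scaling_shifts_log2(self, annotations_4v5):
        report = self._report()
        scaled = report.copy()
        scaled["quantity"] *= 4.0
        a = quantify_all(report, annotations_4v5)
        b = quantify_all(scaled, annotations_4v5)
        diff = (b - a).to_numpy()
        np.testing.assert_allclose(diff[np.isfinite(diff)], 2.0, atol=1e-9)
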