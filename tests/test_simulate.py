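import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diadetect.classify import EvidenceLabel, classify
from diadetect.io import apply_q_filters
from diadetect.simulate import (
    ProteinSpec,
    SyntheticConfig,
    annotations_for,
    generate_report,
    make_study_like_fixture,
)


def prob_config(specs, seed=0, **kw):
    return SyntheticConfig(proteins=tuple(specs), seed=seed, **kw)


class TestGenerateReport:
    def test_certain_detection_fills_every_run(self):
        cfg = prob_config(
            [ProteinSpec("P1", "G1", n_precursors=2, p_dep=1.0, p_non=1.0)]
        )
        report, truth = generate_report(cfg)
        core = report[~report["protein_group"].str.startswith("DECOY-")]
        assert core["run_id"].nunique() == 9
        assert len(core) == 9 * 2  # every precursor in every run
        assert truth["planted_class"].iloc[0] == "shared"

    def test_same_seed_is_byte_identical(self):
        specs = [
            ProteinSpec(f"P{i}", n_precursors=2, p_dep=0.8, p_non=0.3) for i in range(10)
        ]
        r1, t1 = generate_report(prob_config(specs, seed=33))
        r2, t2 = generate_report(prob_config(specs, seed=33))
        assert r1.to_csv() == r2.to_csv()
        assert t1.to_csv() == t2.to_csv()

    def test_seed_changes_realization_not_truth_classes(self):
        specs = [
            ProteinSpec(f"P{i}", n_precursors=1, p_dep=0.9, p_non=0.1) for i in range(20)
        ]
        r1, t1 = generate_report(prob_config(specs, seed=1))
        r2, t2 = generate_report(prob_config(specs, seed=2))
        assert r1.to_csv() != r2.to_csv()
        assert t1["planted_class"].tolist() == t2["planted_class"].tolist()

    def test_empirical_detection_rate_matches_probability(self):
        # 500 proteins x 4 Dep runs = 2000 Bernoulli draws at p = 0.75
        p = 0.75
        specs = [
            ProteinSpec(f"P{i:03d}", n_precursors=1, p_dep=p, p_non=p)
            for i in range(500)
        ]
        cfg = prob_config(specs, seed=9, q_spurious_fraction=0.0)
        report, _ = generate_report(cfg)
        dep_runs = {f"Dep_{i}" for i in range(1, 5)}
        n_detected = len(report[report["run_id"].isin(dep_runs)])
        n_draws = 500 * 4
        rate = n_detected / n_draws
        se = math.sqrt(p * (1 - p) / n_draws)
        assert abs(rate - p) <= 3 * se

    def test_spurious_rows_exceed_q_threshold_and_are_attributable(self):
        specs = [
            ProteinSpec(f"P{i}", n_precursors=2, p_dep=1.0, p_non=1.0) for i in range(20)
        ]
        cfg = prob_config(specs, seed=4, q_spurious_fraction=0.1)
        report, _ = generate_report(cfg)
        decoys = report[report["protein_group"].str.startswith("DECOY-")]
        assert len(decoys) > 0
        assert (decoys["q_global"] > 0.01).all()
        kept, rejections = apply_q_filters(report)
        assert rejections["q_global"] == len(decoys)
        assert not kept["protein_group"].str.startswith("DECOY-").any()

    def test_mnar_missingness_decreases_with_abundance(self):
        # abundance mode: probability of censoring falls as the mean rises
        rates = []
        for mean in (9.0, 10.0, 11.0, 12.0):
            specs = [
                ProteinSpec(
                    f"P{i}", n_precursors=1, mean_log2_dep=mean, mean_log2_non=mean
                )
                for i in range(150)
            ]
            cfg = prob_config(specs, seed=17, q_spurious_fraction=0.0, lod_log2=10.0)
            report, _ = generate_report(cfg)
            rates.append(len(report) / (150 * 9))
        assert rates == sorted(rates)
        assert rates[0] < 0.5 < rates[-1]

    def test_classifier_frequency_matches_binomial_closed_form(self):
        # fraction labeled strong_dep at (p_dep=0.75, p_non=0.20) should equal
        # P(k_dep >= 3) * P(k_non <= 1) from the binomial pmfs
        p_dep, p_non = 0.75, 0.20
        n_prot = 10_000
        rng = np.random.default_rng(99)
        k_dep = rng.binomial(4, p_dep, n_prot)
        k_non = rng.binomial(5, p_non, n_prot)
        frac = np.mean(
            [
                classify(kd, 4, kn, 5) is EvidenceLabel.STRONG_DEP
                for kd, kn in zip(k_dep, k_non)
            ]
        )
        expected = stats.binom.sf(2, 4, p_dep) * stats.binom.cdf(1, 5, p_non)
        se = math.sqrt(expected * (1 - expected) / n_prot)
        assert abs(frac - expected) <= 3 * se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(proteins=())
        with pytest.raises(ValueError):
            prob_config([ProteinSpec("P", p_dep=1.5, p_non=0.0)])
        with pytest.raises(ValueError):
            ProteinSpec("P")  # neither mode configured


class TestStudyLikeFixture:
    def test_truth_table_class_counts(self, study_like):
        _, truth, _ = study_like
        counts = truth["planted_class"].value_counts()
        assert counts["dep_preferred"] == 140
        assert counts["nondep_preferred"] == 67
        assert counts["shared"] == 404
        assert len(truth) == 611

    def test_annotation_shape(self, study_like):
        _, _, ann = study_like
        assert ann["group"].value_counts().to_dict() == {"NonDep": 5, "Dep": 4}

    def test_deterministic_detection_recovered_end_to_end(self):
        # planted probabilities 1.0 vs 0.0 leave no stochastic censoring:
        # the pipeline must recover every planted class exactly
        specs = (
            [ProteinSpec(f"D{i}", n_precursors=2, p_dep=1.0, p_non=0.0) for i in range(10)]
            + [ProteinSpec(f"N{i}", n_precursors=2, p_dep=0.0, p_non=1.0) for i in range(5)]
            + [ProteinSpec(f"S{i}", n_precursors=2, p_dep=1.0, p_non=1.0) for i in range(20)]
        )
        cfg = prob_config(specs, seed=5, q_spurious_fraction=0.0)
        report, truth = generate_report(cfg)
        from diadetect.detection import detection_profiles, venn_partition
        from diadetect.quant import quantify_all

        ann = annotations_for(cfg)
        qmat = quantify_all(report, ann)
        venn = venn_partition(detection_profiles(qmat, ann))
        assert venn.sizes() == {
            "dep_unique": 10,
            "nondep_unique": 5,
            "shared": 20,
            "undetected_in_both": 0,
        }
        assert venn.dep_unique == {f"D{i}" for i in range(10)}
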