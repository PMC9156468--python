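"""ROC/Youden/bootstrap diagnostics against pair-count and sklearn oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import thyromir as tm
from thyromir.datasets import study_annotations
from thyromir.diagnostics import DiagnosticsError, contingency_at_cutoff, mutation_contingency


def pair_count_auc(scores, labels):
    """Concordant-pair oracle: P(score_mal < score_ben) + half credit for ties."""
    mal = [s for s, y in zip(scores, labels) if y == "malignant"]
    ben = [s for s, y in zip(scores, labels) if y == "benign"]
    total = 0.0
    for a in mal:
        for b in ben:
            total += 1.0 if a < b else (0.5 if a == b else 0.0)
    return total / (len(mal) * len(ben))


class TestLabels:
    def test_histology_mapping(self):
        ann = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3"],
                "histology": ["FA", "FV-PTC", "NIFTP"],
                "cytology": "TIR3A",
                "mutation_status": "wild_type",
                "qc_flag": "pass",
            }
        )
        labels = tm.label_malignancy(ann)
        assert labels.tolist() == ["benign", "malignant", "malignant"]

    def test_study_cohort_label_totals(self):
        labels = tm.label_malignancy(study_annotations())
        assert (labels == "benign").sum() == 41
        assert (labels == "malignant").sum() == 57

    def test_unknown_histology_rejected(self):
        ann = pd.DataFrame(
            {"sample_id": ["S1"], "histology": ["PTC"], "cytology": "TIR3A",
             "mutation_status": "wild_type", "qc_flag": "pass"}
        )
        with pytest.raises(DiagnosticsError, match="PTC"):
            tm.label_malignancy(ann)


class TestROC:
    def test_perfect_separation_has_auc_one(self):
        curve = tm.roc_curve([1, 2, 3, 4, 5], ["malignant"] * 3 + ["benign"] * 2)
        assert curve.auc == 1.0

    def test_all_tied_scores_have_auc_half(self):
        curve = tm.roc_curve([2, 2, 2, 2], ["malignant", "benign"] * 2)
        assert curve.auc == 0.5
        assert curve.youden_j == 0.0

    def test_one_class_rejected(self):
        with pytest.raises(DiagnosticsError, match="both classes"):
            tm.roc_curve([1, 2], ["benign", "benign"])

    @given(
        st.lists(st.integers(min_value=0, max_value=9), min_size=2, max_size=30),
        st.data(),
    )
    def test_auc_matches_pair_count_oracle(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.sampled_from(["benign", "malignant"]), min_size=n, max_size=n)
        )
        if len(set(labels)) < 2:
            labels[0], labels[1] = "benign", "malignant"
        curve = tm.roc_curve(scores, labels)
        assert curve.auc == pytest.approx(pair_count_auc(scores, labels))

    def test_auc_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        y = rng.random(40) < 0.5
        y[:2] = [True, False]
        labels = np.where(y, "malignant", "benign")
        curve = tm.roc_curve(scores, labels)
        # sklearn scores "positive = high", our malignant class scores low
        assert curve.auc == pytest.approx(roc_auc_score(y, -scores))

    def test_negating_scores_and_orientation_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.4, "malignant", "benign")
        labels[:2] = ["malignant", "benign"]
        a = tm.roc_curve(scores, labels)
        b = tm.roc_curve(-scores, labels, orientation="high_means_malignant")
        assert a.auc == pytest.approx(b.auc)
        assert a.youden_j == pytest.approx(b.youden_j)
        assert np.allclose(a.sensitivity, b.sensitivity)
        assert np.allclose(a.specificity, b.specificity)


class TestYouden:
    def test_perfect_separation_cutoff_is_midpoint(self):
        curve = tm.roc_curve([1, 2, 5, 6], ["malignant", "malignant", "benign", "benign"])
        cutoff, j = tm.youden_cutoff(curve)
        assert cutoff == pytest.approx(3.5)
        assert j == pytest.approx(1.0)

    def test_tie_broken_toward_higher_sensitivity(self):
        # thresholds 1.5 and 4.5 both reach J = 0.5; 4.5 has sensitivity 1
        curve = tm.roc_curve([1, 4, 2, 5], ["malignant", "malignant", "benign", "benign"])
        cutoff, j = tm.youden_cutoff(curve)
        assert j == pytest.approx(0.5)
        assert cutoff == pytest.approx(4.5)

    def test_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            scores = rng.integers(0, 6, size=12).astype(float)
            labels = np.where(rng.random(12) < 0.5, "malignant", "benign")
            labels[:2] = ["malignant", "benign"]
            curve = tm.roc_curve(scores, labels)
            j_grid = curve.sensitivity + curve.specificity - 1.0
            assert curve.youden_j == pytest.approx(j_grid.max())
            table = contingency_at_cutoff(scores, labels, curve.youden_cutoff)
            perf = tm.performance_from_contingency(table)
            assert perf["sensitivity"] + perf["specificity"] - 1 == pytest.approx(
                curve.youden_j
            )


class TestContingency:
    def test_symmetric_unit_table_gives_half_everywhere(self):
        perf = tm.performance_from_contingency(tm.ContingencyTable2x2(1, 1, 1, 1))
        assert all(v == pytest.approx(0.5) for v in perf.values())

    def test_error_free_table_gives_ones(self):
        perf = tm.performance_from_contingency(tm.ContingencyTable2x2(5, 0, 0, 7))
        assert all(v == pytest.approx(1.0) for v in perf.values())

    def test_zero_denominator_is_nan_not_zero(self):
        perf = tm.performance_from_contingency(tm.ContingencyTable2x2(0, 0, 3, 4))
        assert np.isnan(perf["ppv"])
        assert perf["npv"] == pytest.approx(4 / 7)

    def test_mutation_marker_contingency_from_study_cohort(self):
        table = mutation_contingency(study_annotations())
        assert (table.tp, table.fp, table.fn, table.tn) == (30, 2, 27, 39)


class TestBootstrap:
    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, "malignant", "benign")
        labels[:2] = ["malignant", "benign"]
        a = tm.bootstrap_ci(scores, labels, n_reps=200, seed=42)
        b = tm.bootstrap_ci(scores, labels, n_reps=200, seed=42)
        assert a == b

    def test_auc_fast_path_agrees_with_loop_path(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.5, "malignant", "benign")
        labels[:2] = ["malignant", "benign"]
        fast = tm.bootstrap_ci(scores, labels, n_reps=300, seed=1, metrics=("auc",))
        full = tm.bootstrap_ci(scores, labels, n_reps=300, seed=1)
        assert fast["auc"] == pytest.approx(full["auc"])

    def test_perfect_separation_collapses_cis_to_one(self):
        scores = [1, 2, 3, 7, 8, 9]
        labels = ["malignant"] * 3 + ["benign"] * 3
        cis = tm.bootstrap_ci(scores, labels, n_reps=100, seed=0)
        for metric, (lo, hi) in cis.items():
            assert lo == pytest.approx(1.0)
            assert hi == pytest.approx(1.0)


class TestEvaluateScore:
    def test_subset_modes_and_errors(self, preprocessed_default, default_cohort):
        config, _, annotations, _ = default_cohort
        filtered, _, _ = preprocessed_default
        model = tm.MiRScoreModel(marker_ids=config.marker_ids)
        wt = tm.evaluate_score(filtered, model, annotations, "wild_type_only", n_reps=50)
        full = tm.evaluate_score(filtered, model, annotations, "all", n_reps=50)
        assert wt.n_samples == 39  # 21 wt FA + 15 wt FV-PTC + 3 wt NIFTP
        assert full.n_samples == 58
        assert 0 < wt.prevalence < 1
        with pytest.raises(DiagnosticsError, match="subset"):
            tm.evaluate_score(filtered, model, annotations, "mutated_only")

    def test_repressed_mutated_samples_do_not_hurt_all_sample_auc(
        self, preprocessed_default, default_cohort
    ):
        """Mutated samples repress the markers further, so the all-sample
        AUC is at least as high as the wild-type AUC on synthetic cohorts."""
        config, _, annotations, _ = default_cohort
        filtered, _, _ = preprocessed_default
        model = tm.MiRScoreModel(marker_ids=config.marker_ids)
        wt = tm.evaluate_score(filtered, model, annotations, "wild_type_only", n_reps=10)
        full = tm.evaluate_score(filtered, model, annotations, "all", n_reps=10)
        assert full.metrics["auc"][0] >= wt.metrics["auc"][0] - 0.05

    def test_single_class_subset_rejected(self, preprocessed_default):
        filtered, _, _ = preprocessed_default
        ann = pd.DataFrame(
            {
                "sample_id": filtered.sample_ids[:4],
                "cytology": "TIR3A",
                "histology": "FA",
                "mutation_status": "wild_type",
                "qc_flag": "pass",
            }
        )
        model = tm.MiRScoreModel(marker_ids=("hsa-miR-7-5p",))
        with pytest.raises(DiagnosticsError):
            tm.evaluate_score(filtered, model, ann, "all", n_reps=10)
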