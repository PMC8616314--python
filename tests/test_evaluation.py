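"""Metrics, Wilcoxon comparisons, sweeps and top-feature analyses."""

import numpy as np
import pytest

from rfomics.evaluation import (
    append_covariates,
    class_mean_threshold_analysis,
    compute_metrics,
    paired_wilcoxon,
    reader_comparison,
    sequence_sweep,
    top_feature_frequency,
    voi_sweep,
)
from rfomics.feature_io import FeatureTable
from rfomics.model_zoo import CVReport, ModelSpec

from conftest import make_bundle

FAST_ZOO = {"selectors": ["anova_f"], "classifiers": ["logistic"],
            "selector_k": 2}


def brute_force_auc(scores, labels):
    """All-pairs concordance count, ties credited 0.5."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_worked_auc(self):
        m = compute_metrics([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert m.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        m = compute_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m.auc == 1.0 and m.acc == 1.0 and m.sen == 1.0 and m.spe == 1.0

    def test_all_ties_auc_half(self):
        m = compute_metrics([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert m.auc == pytest.approx(0.5)

    def test_confusion_identities(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        m = compute_metrics(scores, labels)
        n = len(labels)
        assert m.tp + m.fp + m.tn + m.fn == n
        assert m.acc == pytest.approx((m.tp + m.tn) / n)
        assert m.sen == pytest.approx(m.tp / (m.tp + m.fn))
        assert m.spe == pytest.approx(m.tn / (m.tn + m.fp))

    def test_rank_auc_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(10, 200))
            # quantized scores to force ties
            scores = np.round(rng.uniform(size=n), 1)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            m = compute_metrics(scores, labels)
            assert m.auc == pytest.approx(brute_force_auc(scores, labels))

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError, match="one class"):
            compute_metrics([0.1, 0.9], [1, 1])


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        out = paired_wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["degenerate"] and not out["significant"]

    def test_constant_shift_significant(self):
        """n=20 one-direction shift: exact signed-rank p < 0.05."""
        rng = np.random.default_rng(2)
        y = rng.standard_normal(20)
        out = paired_wilcoxon(y + 1.0, y)
        assert out["p_value"] < 0.05 and out["significant"]

    def test_symmetric_noise_mostly_insignificant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50)
            if paired_wilcoxon(x, y)["p_value"] > 0.05:
                hits += 1
        assert hits >= 15  # null should rarely reject


class TestVoiSweep:
    def test_bookkeeping_and_signal_ranking(self):
        rng = np.random.default_rng(4)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        ids = [f"s{i}" for i in range(n)]
        feats = [f"f{j}" for j in range(4)]

        def table(delta):
            v = rng.standard_normal((n, 4))
            v[:, :2] += delta * labels[:, None]
            return FeatureTable("x", ids, feats, v, labels=labels)

        tables = {("T1WI", "ET"): table(2.5), ("T1WI", "pTE"): table(0.0)}
        report = voi_sweep(tables, labels, zoo_config=FAST_ZOO, folds=3, seed=0)
        # 2 cells x 1 model x 3 folds records
        assert len(report.records) == 6
        means = report.cell_mean_auc()
        assert means["T1WI/ET"] > means["T1WI/pTE"]
        assert abs(means["T1WI/pTE"] - 0.5) < 0.35  # pure noise, tiny n
        assert report.best_cell() == "T1WI/ET"

    def test_cell_means_invariant_to_record_order(self):
        rng = np.random.default_rng(5)
        from rfomics.evaluation import SweepReport
        records = [{"cell": c, "model": m, "fold": f,
                    "auc": float(rng.uniform())}
                   for c in ("a", "b") for m in ("m1", "m2") for f in range(3)]
        r1 = SweepReport("voi", list(records))
        rng.shuffle(records)
        r2 = SweepReport("voi", records)
        m1, m2 = r1.cell_mean_auc(), r2.cell_mean_auc()
        assert m1 == pytest.approx(m2)


class TestSequenceSweep:
    def test_singleton_matches_direct_zoo(self):
        bundle, labels = make_bundle(n=40, m=5, p=2, delta=1.5, seed=6)
        from rfomics.model_zoo import build_model_zoo, run_stratified_cv
        report = sequence_sweep(bundle, labels, zoo_config=FAST_ZOO, folds=3,
                                seed=3, subsets=[("M0",)])
        spec = build_model_zoo(FAST_ZOO)[0]
        from rfomics.utils import derive_seed
        direct = run_stratified_cv(spec, bundle.tables[0], labels, folds=3,
                                   seed=derive_seed(3, "sequence_sweep", "M0"))
        got = [r["auc"] for r in report.records]
        assert got == direct.fold_auc

    def test_pair_uses_fusion_and_records_folds(self):
        bundle, labels = make_bundle(n=40, m=5, p=2, delta=1.0, seed=7)
        report = sequence_sweep(bundle, labels, zoo_config=FAST_ZOO, folds=3,
                                seed=0, subsets=[("M0", "M1")])
        assert {r["cell"] for r in report.records} == {"M0+M1"}
        assert len(report.records) == 3


class TestReaderComparison:
    def test_perfect_reader_and_mdt_vote(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 1], 15)
        scores = np.clip(labels * 0.8 + rng.uniform(0, 0.2, 30), 0, 1)
        readers = {
            "r1": labels.copy(),                       # perfect
            "r2": labels.copy(),
            "r3": 1 - labels,                          # always wrong
        }
        out = reader_comparison(scores, labels, readers, n_bootstrap=100,
                                seed=0)
        assert out["readers"]["r1"].acc == 1.0
        assert out["readers"]["r1"].sen == 1.0
        # MDT plurality (1,1,0 correct votes) follows the majority
        assert out["mdt"].acc == 1.0
        assert set(out["comparisons"]) == {"r1", "r2", "r3", "MDT"}

    def test_reader_equal_to_model_degenerate(self):
        labels = np.repeat([0, 1], 10)
        scores = labels.astype(float)
        out = reader_comparison(scores, labels, {"twin": labels.copy()},
                                n_bootstrap=50, seed=1)
        assert out["comparisons"]["twin"]["degenerate"]

    def test_misaligned_reader_rejected(self):
        labels = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError, match="misaligned"):
            reader_comparison(labels.astype(float), labels,
                              {"r": np.array([0, 1])})


def _report(model_id, auc, feats):
    sel, clf = model_id.split("+")
    return CVReport(spec=ModelSpec(sel, clf), fold_auc=[auc],
                    fold_acc=[auc], fold_sen=[auc], fold_spe=[auc],
                    fold_selected_features=[list(feats)])


class TestTopFeatures:
    def test_counts_and_floor(self):
        reports = [_report("anova_f+logistic", 0.9, ["f1", "f2"]),
                   _report("mrmr+logistic", 0.7, ["f3"])]
        out = top_feature_frequency(reports, auc_floor=0.8)
        assert out.counts == {"f1": 1, "f2": 1}
        assert out.n_qualifying == 1

    def test_unreachable_floor_empty(self):
        reports = [_report("anova_f+logistic", 0.9, ["f1"])]
        out = top_feature_frequency(reports, auc_floor=1.1)
        assert out.counts == {} and out.n_qualifying == 0

    def test_ranked_counts_non_increasing(self):
        reports = [_report("anova_f+logistic", 0.9, ["f1", "f2"]),
                   _report("mrmr+logistic", 0.95, ["f1"])]
        ranked = top_feature_frequency(reports, 0.8).ranked()
        counts = [c for _, c in ranked]
        assert counts == sorted(counts, reverse=True)
        assert ranked[0] == ("f1", 2)


class TestCovariates:
    def test_appended_columns_enter_the_table(self):
        t = FeatureTable("fused", ["a", "b", "c"], ["f1"],
                         np.array([[1.0], [2.0], [3.0]]),
                         labels=np.array([0, 1, 0]))
        out = append_covariates(t, {"age": [50.0, 60.0, 70.0],
                                    "location": [0, 1, 1]})
        assert out.feature_names == ["f1", "age", "location"]
        np.testing.assert_array_equal(out.values[:, 1], [50, 60, 70])
        np.testing.assert_array_equal(out.labels, t.labels)

    def test_misaligned_or_colliding_covariate_rejected(self):
        t = FeatureTable("fused", ["a", "b"], ["f1"], np.zeros((2, 1)))
        with pytest.raises(ValueError, match="per sample"):
            append_covariates(t, {"age": [1.0]})
        with pytest.raises(ValueError, match="collides"):
            append_covariates(t, {"f1": [1.0, 2.0]})


class TestThresholdAnalysis:
    def test_separated_classes(self):
        t = FeatureTable("x", list("abcdef"), ["f"],
                         np.array([[1.0], [2.0], [3.0], [5.0], [6.0], [7.0]]),
                         labels=np.array([0, 0, 0, 1, 1, 1]))
        row = class_mean_threshold_analysis(t).rows[0]
        assert row["M"] == pytest.approx(4.0)
        assert row["neg_below_pct"] == 100.0
        assert row["pos_above_pct"] == 100.0

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(9)
        v = rng.standard_normal((200, 1))
        t = FeatureTable("x", [f"s{i}" for i in range(200)], ["f"], v,
                         labels=np.tile([0, 1], 100))
        row = class_mean_threshold_analysis(t).rows[0]
        assert 30 < row["pos_below_pct"] < 70
        assert row["pos_below_pct"] + row["pos_above_pct"] == pytest.approx(100)

    def test_value_at_M_counts_below(self):
        t = FeatureTable("x", list("abcd"), ["f"],
                         np.array([[0.0], [2.0], [2.0], [4.0]]),
                         labels=np.array([0, 0, 1, 1]))
        row = class_mean_threshold_analysis(t).rows[0]
        assert row["M"] == pytest.approx(2.0)
        # both the 2.0 values (one per class) count as below
        assert row["neg_below_pct"] == 100.0
        assert row["pos_below_pct"] == 50.0
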