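"""Between-class scatter, whitening, and the fitted fusion transform.

The rank-1 structure of the two-class scatter admits a closed-form
oracle: with d = xbar_1 - xbar_0, S = (n1*n0/n) d d^T, so the single
retained eigenpair is lambda = (n1*n0/n)|d|^2, q = d/|d|, and the fused
row is q^T X / sqrt(lambda) up to sign. Tests compare the
implementation against that independent route.
"""

import numpy as np
import pytest

from rfomics.feature_io import FeatureTable, ModalityBundle
from rfomics.fusion import (
    between_class_scatter,
    enumerate_sequence_combinations,
    apply_feature_fusion,
    fit_feature_fusion,
    unitize_scatter,
)

from conftest import make_bundle

WORKED_X = np.array([[1.0, 1.0, 3.0, 3.0], [0.0, 2.0, 2.0, 4.0]])
WORKED_LABELS = np.array([0, 0, 1, 1])


def rank1_oracle(X, labels):
    """Closed-form fused row for the two-class scatter (sign-free)."""
    X = np.asarray(X, float)
    labels = np.asarray(labels, int)
    n = len(labels)
    n1, n0 = (labels == 1).sum(), (labels == 0).sum()
    d = X[:, labels == 1].mean(axis=1) - X[:, labels == 0].mean(axis=1)
    lam = (n1 * n0 / n) * d @ d
    q = d / np.linalg.norm(d)
    return q @ X / np.sqrt(lam), lam, q


class TestScatter:
    def test_worked_example(self):
        sc = between_class_scatter(WORKED_X, WORKED_LABELS)
        np.testing.assert_allclose(sc.S, [[4, 4], [4, 4]])
        np.testing.assert_allclose(sc.class_means, [[1, 1], [3, 3]])
        np.testing.assert_allclose(sc.grand_mean, [2, 2])
        assert sc.class_sizes == (2, 2)

    def test_equal_class_means_give_zero_scatter(self):
        X = np.array([[1.0, 2.0, 1.0, 2.0], [0.0, 1.0, 0.0, 1.0]])
        sc = between_class_scatter(X, [0, 0, 1, 1])
        np.testing.assert_allclose(sc.S, 0, atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 20))
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        perm = rng.permutation(20)
        a = between_class_scatter(X, labels).S
        b = between_class_scatter(X[:, perm], labels[perm]).S
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            between_class_scatter(WORKED_X, [1, 1, 1, 1])

    def test_closed_form_rank1(self):
        """S equals (n1 n0 / n) d d^T for two classes."""
        rng = np.random.default_rng(1)
        for p in (2, 3, 4):
            X = rng.standard_normal((p, 30))
            labels = np.r_[np.zeros(12, int), np.ones(18, int)]
            sc = between_class_scatter(X, labels)
            d = sc.class_means[1] - sc.class_means[0]
            np.testing.assert_allclose(sc.S, (18 * 12 / 30) * np.outer(d, d),
                                       atol=1e-10)
            assert np.linalg.matrix_rank(sc.S, tol=1e-8) <= 1


class TestUnitize:
    def test_worked_example(self):
        W, eigvals, degen = unitize_scatter(np.array([[4.0, 4.0], [4.0, 4.0]]))
        np.testing.assert_allclose(sorted(eigvals), [0, 8], atol=1e-12)
        np.testing.assert_allclose(W, [[0.25], [0.25]])
        assert not degen

    def test_zero_scatter_degenerate_fallback(self):
        for p in (2, 3, 4):
            W, _, degen = unitize_scatter(np.zeros((p, p)))
            assert degen
            np.testing.assert_allclose(W, np.full((p, 1), 1 / np.sqrt(p)))

    def test_whitening_property_random(self):
        """W^T S W = I_r on random rank-1 PSD scatters, all p."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.integers(2, 5)
            d = rng.standard_normal(p)
            S = rng.uniform(0.5, 20) * np.outer(d, d)
            W, _, degen = unitize_scatter(S)
            assert not degen
            np.testing.assert_allclose(W.T @ S @ W, np.eye(W.shape[1]),
                                       atol=1e-8)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            unitize_scatter(np.array([[1.0, 2.0], [0.0, 1.0]]))


def _bundle_from_X(X, labels):
    """Wrap a p x n matrix as a single-feature bundle (pre-standardized off)."""
    p, n = X.shape
    tables = [
        FeatureTable(f"M{k}", [f"s{i}" for i in range(n)], ["f0"],
                     X[k][:, None], labels=labels)
        for k in range(p)
    ]
    return ModalityBundle(tables)


class TestFitFusion:
    def test_worked_example_fused_row(self):
        """Unstandardized worked matrix through scatter+unitize+project."""
        sc = between_class_scatter(WORKED_X, WORKED_LABELS)
        W, _, _ = unitize_scatter(sc.S)
        np.testing.assert_allclose((W.T @ WORKED_X)[0], [0.25, 0.75, 1.25, 1.75])

    def test_oracle_equivalence_random(self):
        """Fused values match the closed-form rank-1 eigensolve."""
        rng = np.random.default_rng(3)
        for p in (2, 3, 4):
            n = 40
            labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
            X = rng.standard_normal((p, n)) + 0.8 * labels
            bundle = _bundle_from_X(X, labels)
            transform, fused = fit_feature_fusion(bundle, labels)
            # oracle runs on the same standardized matrix the fit used
            from rfomics.feature_io import apply_standardizer
            z = apply_standardizer(transform.standardizer, bundle)
            Xz = np.vstack([t.values[:, 0] for t in z.tables])
            expect, _, _ = rank1_oracle(Xz, labels)
            got = fused.values[:, 0]
            err = min(np.abs(got - expect).max(), np.abs(got + expect).max())
            assert err < 1e-8

    def test_direction_recovery(self):
        """Retained eigenvector is parallel to the class-mean difference."""
        rng = np.random.default_rng(4)
        n = 60
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        X = rng.standard_normal((3, n))
        X += np.array([1.0, -0.5, 2.0])[:, None] * labels
        sc = between_class_scatter(X, labels)
        W, lam, _ = unitize_scatter(sc.S)
        d = sc.class_means[1] - sc.class_means[0]
        w = W[:, 0]
        cos = abs(w @ d) / (np.linalg.norm(w) * np.linalg.norm(d))
        assert cos >= 1 - 1e-8

    def test_positive_class_has_larger_fused_mean(self, small_bundle):
        bundle, labels = small_bundle
        _, fused = fit_feature_fusion(bundle, labels)
        pos = fused.values[labels == 1].mean(axis=0)
        neg = fused.values[labels == 0].mean(axis=0)
        assert np.all(pos >= neg - 1e-12)

    def test_duplicated_modality_preserves_ranking(self):
        """p=2 with identical rows: fused values rank like the modality."""
        rng = np.random.default_rng(5)
        n = 30
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        x = rng.standard_normal(n) + labels
        X = np.vstack([x, x])
        bundle = _bundle_from_X(X, labels)
        _, fused = fit_feature_fusion(bundle, labels)
        got = fused.values[:, 0]
        assert np.array_equal(np.argsort(got), np.argsort(x))

    def test_apply_reproduces_training_fusion(self, small_bundle):
        bundle, labels = small_bundle
        transform, fused = fit_feature_fusion(bundle, labels)
        again = apply_feature_fusion(transform, bundle)
        np.testing.assert_allclose(again.values, fused.values, atol=1e-12)

    def test_apply_single_sample_without_labels(self, small_bundle):
        bundle, labels = small_bundle
        transform, _ = fit_feature_fusion(bundle, labels)
        one = ModalityBundle([
            FeatureTable(t.modality_id, t.sample_ids[:1], t.feature_names,
                         t.values[:1])
            for t in bundle.tables
        ])
        fused = apply_feature_fusion(transform, one)
        assert fused.n_samples == 1
        assert fused.labels is None

    def test_modality_order_mismatch_rejected(self, small_bundle):
        bundle, labels = small_bundle
        transform, _ = fit_feature_fusion(bundle, labels)
        flipped = bundle.select_modalities(bundle.modality_ids[::-1])
        with pytest.raises(ValueError, match="order"):
            apply_feature_fusion(transform, flipped)

    def test_single_modality_rejected(self):
        bundle, labels = make_bundle(p=1)
        with pytest.raises(ValueError, match="p >= 2"):
            fit_feature_fusion(bundle, labels)

    def test_registry_sized_output(self):
        from rfomics.registry import default_registry
        from rfomics.synthetic import default_study_scenario

        reg = default_registry()
        tr_b, tr_y, _, _ = default_study_scenario(seed=0)
        transform, fused = fit_feature_fusion(tr_b, tr_y, registry=reg)
        assert fused.n_features == len(reg) == 109


class TestSequenceCombinations:
    def test_fifteen_subsets(self):
        subsets = enumerate_sequence_combinations(["A", "B", "C", "D"])
        assert len(subsets) == 15
        sizes = [len(s) for s in subsets]
        assert sizes == [1] * 4 + [2] * 6 + [3] * 4 + [4]
        assert subsets == enumerate_sequence_combinations(list("ABCD"))

    def test_requires_four_distinct(self):
        with pytest.raises(ValueError):
            enumerate_sequence_combinations(["A", "B", "C"])
        with pytest.raises(ValueError):
            enumerate_sequence_combinations(["A", "A", "B", "C"])
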