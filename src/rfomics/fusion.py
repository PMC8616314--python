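"""Level-1 feature fusion: between-class scatter whitening across modalities.

For each radiomics feature, the values observed on the p MRI sequences
form a data matrix X (p x n: one row per sequence, one column per
sample). The class structure of the training cohort enters through the
between-class scatter matrix

    S = sum_i  n_i (xbar_i - xbar)(xbar_i - xbar)^T,        i = 1..c

where ``xbar_i`` is the class-i mean column of X, ``xbar`` the grand
mean, and ``n_i`` the class sizes. Unitizing S — eigendecomposing
S = Q Λ Qᵀ and taking W = Q_r Λ_r^(−1/2) over the retained eigenpairs —
yields the transformation with WᵀSW = I_r. For a two-class problem S
has rank ≤ 1, so W is a single column and WᵀX compresses X to one fused
row per feature; stacking the m rows gives the fused feature matrix
F (m x n).

The fitted :class:`FusionTransform` stores W per feature together with
the training standardization statistics, so held-out cohorts are fused
by direct application with zero refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .feature_io import (
    FeatureTable,
    ModalityBundle,
    Standardizer,
    apply_standardizer,
    fit_standardizer,
)
from .registry import FeatureRegistry

__all__ = [
    "PerFeatureMatrix",
    "ScatterMatrix",
    "FusionTransform",
    "between_class_scatter",
    "unitize_scatter",
    "fit_feature_fusion",
    "apply_feature_fusion",
    "enumerate_sequence_combinations",
]

#: Relative eigenvalue retention threshold for unitization.
DEFAULT_TOL = 1e-10


@dataclass
class PerFeatureMatrix:
    """The p x n cross-modality matrix of one feature."""

    feature_name: str
    X: np.ndarray  # (p, n)
    modality_order: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (modalities x samples)")
        if self.X.shape[0] != len(self.modality_order):
            raise ValueError("modality_order does not match X rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains NaN/inf")


@dataclass
class ScatterMatrix:
    """Between-class scatter with its constituent class statistics."""

    S: np.ndarray  # (p, p)
    class_sizes: tuple[int, int]
    class_means: np.ndarray  # (2, p), row i = mean of class i
    grand_mean: np.ndarray  # (p,)


def between_class_scatter(X: np.ndarray, labels) -> ScatterMatrix:
    """S = Σ_i n_i (xbar_i − xbar)(xbar_i − xbar)ᵀ over the two classes.

    ``X`` is p x n (columns = samples); ``labels`` is the binary class
    per column.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if labels.shape != (X.shape[1],):
        raise ValueError("labels must have one entry per sample column")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to form the scatter")
    p = X.shape[0]
    grand = X.mean(axis=1)
    S = np.zeros((p, p))
    sizes = []
    means = []
    for cls in (0, 1):
        cols = X[:, labels == cls]
        n_i = cols.shape[1]
        mu = cols.mean(axis=1)
        d = mu - grand
        S += n_i * np.outer(d, d)
        sizes.append(n_i)
        means.append(mu)
    return ScatterMatrix(
        S=S,
        class_sizes=(sizes[0], sizes[1]),
        class_means=np.vstack(means),
        grand_mean=grand,
    )


def unitize_scatter(S: np.ndarray, tol: float = DEFAULT_TOL):
    """Eigen-whiten a symmetric PSD scatter matrix.

    Returns ``(W, eigenvalues, degenerate)`` where W = Q_r Λ_r^(−1/2)
    over eigenpairs with λ > tol·max(λ); then WᵀSW = I_r. If no
    eigenvalue survives (zero between-class scatter) the degenerate
    flag is set and W falls back to the uniform column (1/√p)·1, i.e.
    plain averaging across modalities.

    Sign convention: each retained column is flipped so its
    largest-magnitude entry is positive, making the output
    deterministic across eigensolvers. (The class-aware orientation is
    applied later, in :func:`fit_feature_fusion`.)
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p):
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8 * max(1.0, np.abs(S).max())):
        raise ValueError("S must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    floor = np.finfo(float).tiny
    cutoff = tol * max(eigvals.max(initial=0.0), floor)
    keep = eigvals > cutoff
    if not keep.any():
        return np.full((p, 1), 1.0 / np.sqrt(p)), eigvals, True
    lam = eigvals[keep]
    Q = eigvecs[:, keep]
    # deterministic sign: largest-|entry| component positive
    for j in range(Q.shape[1]):
        i = np.argmax(np.abs(Q[:, j]))
        if Q[i, j] < 0:
            Q[:, j] = -Q[:, j]
    W = Q / np.sqrt(lam)
    return W, eigvals, False


@dataclass
class FusionTransform:
    """Fitted per-feature fusion columns plus standardization state."""

    feature_names: list[str]
    modality_order: list[str]
    W: dict[str, np.ndarray] = field(repr=False)  # feature -> (p, r)
    eigenvalues: dict[str, np.ndarray] = field(repr=False)
    degenerate: dict[str, bool] = field(repr=False)
    standardizer: Standardizer = field(repr=False)
    positive_class: int = 1
    tol: float = DEFAULT_TOL

    @property
    def degenerate_features(self) -> list[str]:
        return [f for f in self.feature_names if self.degenerate[f]]


def _per_feature_matrices(bundle: ModalityBundle):
    """Yield (feature_name, X p x n) for every feature of the bundle."""
    stack = np.stack([t.values for t in bundle.tables])  # (p, n, m)
    for j, name in enumerate(bundle.feature_names):
        yield name, stack[:, :, j]


def fit_feature_fusion(
    bundle: ModalityBundle,
    labels=None,
    registry: FeatureRegistry | None = None,
    tol: float = DEFAULT_TOL,
    positive_class: int = 1,
) -> tuple[FusionTransform, FeatureTable]:
    """Fit the fusion on a training bundle and return (transform, F).

    The bundle is z-scored internally (statistics from these samples,
    stored in the transform). Each feature's W is oriented so the
    positive class has the larger fused mean. The fused table F has one
    row per sample and one column per feature, in registry order when a
    registry is supplied.
    """
    if bundle.n_modalities < 2:
        raise ValueError("fusion requires p >= 2 modalities")
    if labels is None:
        labels = bundle.labels
    if labels is None:
        raise ValueError("labels are required to fit the fusion")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the training bundle")
    if registry is not None:
        from .feature_io import validate_against_registry

        for t in bundle.tables:
            validate_against_registry(t, registry, strict=True)

    std = fit_standardizer(bundle)
    z = apply_standardizer(std, bundle)

    W_map: dict[str, np.ndarray] = {}
    eig_map: dict[str, np.ndarray] = {}
    degen: dict[str, bool] = {}
    fused_cols = []
    pos = labels == positive_class
    neg = ~pos
    for name, X in _per_feature_matrices(z):
        scatter = between_class_scatter(X, labels)
        W, eigvals, is_degen = unitize_scatter(scatter.S, tol=tol)
        fused = W.T @ X  # (r, n); r = 1 for two classes
        if fused.shape[0] != 1:
            # rank(S) <= c-1 = 1 guarantees this; assert defensively
            raise AssertionError("two-class fusion must yield one row")
        row = fused[0]
        if not is_degen and row[pos].mean() < row[neg].mean():
            W = -W
            row = -row
        W_map[name] = W
        eig_map[name] = eigvals
        degen[name] = is_degen
        fused_cols.append(row)
    if all(degen.values()):
        warnings.warn("all features degenerate (zero between-class scatter)",
                      stacklevel=2)

    transform = FusionTransform(
        feature_names=list(z.feature_names),
        modality_order=list(z.modality_ids),
        W=W_map,
        eigenvalues=eig_map,
        degenerate=degen,
        standardizer=std,
        positive_class=positive_class,
        tol=tol,
    )
    fused_table = FeatureTable(
        modality_id="+".join(z.modality_ids),
        sample_ids=list(z.sample_ids),
        feature_names=list(z.feature_names),
        values=np.column_stack(fused_cols),
        labels=labels,
    )
    return transform, fused_table


def apply_feature_fusion(
    transform: FusionTransform, bundle: ModalityBundle
) -> FeatureTable:
    """Fuse a held-out bundle with a trained transform (no refitting)."""
    if bundle.modality_ids != transform.modality_order:
        raise ValueError(
            f"modality order mismatch: transform expects "
            f"{transform.modality_order}, got {bundle.modality_ids}"
        )
    if bundle.feature_names != transform.feature_names:
        raise ValueError("feature names do not match the fitted transform")
    z = apply_standardizer(transform.standardizer, bundle)
    cols = []
    for name, X in _per_feature_matrices(z):
        cols.append((transform.W[name].T @ X)[0])
    return FeatureTable(
        modality_id="+".join(z.modality_ids),
        sample_ids=list(z.sample_ids),
        feature_names=list(z.feature_names),
        values=np.column_stack(cols),
        labels=bundle.labels,
    )


def enumerate_sequence_combinations(modality_ids) -> list[tuple[str, ...]]:
    """All 15 modality subsets of 4 sequences.

    Order: the 4 singletons, the 6 pairs, the 4 triples, then the
    quadruple — each block in the input modality order.
    """
    ids = list(modality_ids)
    if len(ids) != 4 or len(set(ids)) != 4:
        raise ValueError("expected 4 distinct modality ids")
    out: list[tuple[str, ...]] = []
    for size in (1, 2, 3, 4):
        out.extend(combinations(ids, size))
    return out
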