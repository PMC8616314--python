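"""The 15-model grid: five feature selectors x three classifiers.

Each (selector, classifier) pair is one model. Models are evaluated by
stratified five-fold cross-validation on the training cohort — the
selector is refit on the training folds of every split, so feature
selection never sees held-out rows — ranked by mean CV AUC, and the top
three are screened for the consensus stage. The mean CV accuracy of
each screened model becomes its consensus weight input.

Registered selectors: ANOVA F-score, mutual information, ReliefF,
L1-regularized logistic ranking, and mRMR (minimum redundancy, maximum
relevance). Registered classifiers: logistic regression, RBF-kernel
SVM, random forest. Everything is registered by id and swappable
through the zoo config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import compute_metrics
from .feature_io import FeatureTable, ModalityBundle
from .fusion import apply_feature_fusion, fit_feature_fusion
from .utils import derive_seed

__all__ = [
    "ModelSpec",
    "CVReport",
    "TrainedModel",
    "SELECTOR_IDS",
    "CLASSIFIER_IDS",
    "build_model_zoo",
    "run_stratified_cv",
    "rank_models",
    "select_top_k",
    "fit_model",
]

DEFAULT_SELECTOR_K = 10
DEFAULT_FOLDS = 5

# ---------------------------------------------------------------------------
# selector registry: id -> callable(X, y, k, seed) -> column indices
# ---------------------------------------------------------------------------


def _top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores, stable under ties (lowest index)."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return np.sort(order[:k])


def _select_anova_f(X, y, k, seed):
    f, _ = f_classif(X, y)
    return _top_k(np.nan_to_num(f, nan=0.0), k)


def _select_mutual_info(X, y, k, seed):
    mi = mutual_info_classif(X, y, random_state=seed)
    return _top_k(mi, k)


def _select_relieff(X, y, k, seed, n_neighbors: int = 10):
    """ReliefF relevance weights (distance-based margin scores).

    For every sample, features are rewarded for separating it from its
    nearest misses (other class) and penalized for separating it from
    its nearest hits (same class), under L1 feature distances on
    min-max scaled data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, m = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Z = (X - X.min(axis=0)) / span
    weights = np.zeros(m)
    # pairwise L1 distances (n is cohort-scale, a few hundred)
    d = np.abs(Z[:, None, :] - Z[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, np.inf)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        if same.size == 0 or other.size == 0:
            continue
        hits = same[np.argsort(d[i, same])[:n_neighbors]]
        misses = other[np.argsort(d[i, other])[:n_neighbors]]
        weights -= np.abs(Z[hits] - Z[i]).mean(axis=0)
        weights += np.abs(Z[misses] - Z[i]).mean(axis=0)
    return _top_k(weights / n, k)


def _select_l1_logistic(X, y, k, seed):
    """Rank features by |coefficient| of an L1-penalized logistic fit."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    model = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0,
                               random_state=seed, max_iter=1000)
    model.fit((X - mu) / sd, y)
    return _top_k(np.abs(model.coef_[0]), k)


def _select_mrmr(X, y, k, seed):
    """Greedy mRMR: F-score relevance minus mean |Pearson r| redundancy."""
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    relevance = np.nan_to_num(f_classif(X, y)[0], nan=0.0)
    sd = X.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / safe
    corr = np.abs(Z.T @ Z / len(X))
    corr[np.arange(m), np.arange(m)] = 0.0
    selected = [int(np.argmax(relevance))]
    while len(selected) < min(k, m):
        mask = np.ones(m, dtype=bool)
        mask[selected] = False
        redundancy = corr[:, selected].mean(axis=1)
        score = np.where(mask, relevance - redundancy, -np.inf)
        selected.append(int(np.argmax(score)))
    return np.sort(selected)


SELECTORS = {
    "anova_f": _select_anova_f,
    "mutual_info": _select_mutual_info,
    "relieff": _select_relieff,
    "l1_logistic": _select_l1_logistic,
    "mrmr": _select_mrmr,
}
SELECTOR_IDS = tuple(SELECTORS)

# ---------------------------------------------------------------------------
# classifier registry: id -> factory(seed) -> estimator with predict_proba
# ---------------------------------------------------------------------------

CLASSIFIERS = {
    "logistic": lambda seed: LogisticRegression(max_iter=1000, random_state=seed),
    "svm_rbf": lambda seed: SVC(kernel="rbf", probability=True, random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed
    ),
}
CLASSIFIER_IDS = tuple(CLASSIFIERS)


@dataclass(frozen=True)
class ModelSpec:
    """One (selector, classifier) combination of the zoo."""

    selector_id: str
    classifier_id: str
    selector_k: int = DEFAULT_SELECTOR_K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selector_id not in SELECTORS:
            raise ValueError(
                f"unknown selector {self.selector_id!r}; "
                f"registered: {sorted(SELECTORS)}"
            )
        if self.classifier_id not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier_id!r}; "
                f"registered: {sorted(CLASSIFIERS)}"
            )
        if self.selector_k < 1:
            raise ValueError("selector_k must be >= 1")

    @property
    def model_id(self) -> str:
        return f"{self.selector_id}+{self.classifier_id}"


def build_model_zoo(config: dict | None = None) -> list[ModelSpec]:
    """The Cartesian product of configured selectors and classifiers.

    Default config yields the full 15-model grid (5 x 3), selectors
    outer, classifiers inner — a stable, deterministic order.
    """
    config = dict(config or {})
    selectors = config.get("selectors", list(SELECTOR_IDS))
    classifiers = config.get("classifiers", list(CLASSIFIER_IDS))
    k = int(config.get("selector_k", DEFAULT_SELECTOR_K))
    seed = int(config.get("seed", 0))
    return [
        ModelSpec(selector_id=s, classifier_id=c, selector_k=k, seed=seed)
        for s in selectors
        for c in classifiers
    ]


@dataclass
class CVReport:
    """Cross-validated performance record of one ModelSpec."""

    spec: ModelSpec
    fold_auc: list[float]
    fold_acc: list[float]
    fold_sen: list[float]
    fold_spe: list[float]
    fold_selected_features: list[list[str]]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def mean_acc(self) -> float:
        """Mean fold accuracy — the ensemble-weight input acc_i."""
        return float(np.mean(self.fold_acc))

    def summary(self) -> dict:
        agg = {}
        for name, vals in (("auc", self.fold_auc), ("acc", self.fold_acc),
                           ("sen", self.fold_sen), ("spe", self.fold_spe)):
            agg[f"mean_{name}"] = float(np.mean(vals))
            agg[f"sd_{name}"] = float(np.std(vals, ddof=1))
        return {"model": self.spec.model_id, "folds": len(self.fold_auc), **agg}


def _extract_xy(table: FeatureTable, labels):
    labels = np.asarray(labels, dtype=int)
    if len(labels) != table.n_samples:
        raise ValueError("labels do not match table rows")
    return table.values, labels


def run_stratified_cv(
    spec: ModelSpec,
    data: FeatureTable | ModalityBundle,
    labels,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    fuse_in_fold: bool = False,
) -> CVReport:
    """Stratified k-fold CV of one model.

    The selector (and, when ``fuse_in_fold`` is set and ``data`` is a
    ModalityBundle, the feature-fusion transform) is refit on the
    training folds of every split; the held-out fold is only ever
    transformed and scored. Deterministic under ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if fuse_in_fold and not isinstance(data, ModalityBundle):
        raise ValueError("fuse_in_fold requires a ModalityBundle")

    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=derive_seed(seed, "cv_shuffle"))
    n = len(labels)
    report = CVReport(spec=spec, fold_auc=[], fold_acc=[], fold_sen=[],
                      fold_spe=[], fold_selected_features=[])
    for fold_idx, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        if fuse_in_fold:
            ids = data.sample_ids
            tr_bundle = data.subset([ids[i] for i in tr])
            te_bundle = data.subset([ids[i] for i in te])
            transform, fused_tr = fit_feature_fusion(tr_bundle, labels[tr])
            fused_te = apply_feature_fusion(transform, te_bundle)
            X_tr, X_te = fused_tr.values, fused_te.values
            feature_names = fused_tr.feature_names
        else:
            table = data if isinstance(data, FeatureTable) else data.tables[0]
            X, _ = _extract_xy(table, labels)
            X_tr, X_te = X[tr], X[te]
            feature_names = table.feature_names
        y_tr, y_te = labels[tr], labels[te]

        fold_seed = derive_seed(seed, spec.model_id, "fold", fold_idx)
        k = min(spec.selector_k, X_tr.shape[1])
        cols = SELECTORS[spec.selector_id](X_tr, y_tr, k, fold_seed)
        clf = CLASSIFIERS[spec.classifier_id](fold_seed)
        clf.fit(X_tr[:, cols], y_tr)
        scores = clf.predict_proba(X_te[:, cols])[:, list(clf.classes_).index(1)]
        m = compute_metrics(scores, y_te)
        report.fold_auc.append(m.auc)
        report.fold_acc.append(m.acc)
        report.fold_sen.append(m.sen)
        report.fold_spe.append(m.spe)
        report.fold_selected_features.append([feature_names[c] for c in cols])
    return report


def rank_models(reports: list[CVReport]) -> list[CVReport]:
    """Sort by mean AUC desc, ties by mean accuracy desc, then model id."""
    if not reports:
        raise ValueError("nothing to rank")
    return sorted(
        reports,
        key=lambda r: (-r.mean_auc, -r.mean_acc, r.spec.model_id),
    )


@dataclass
class TrainedModel:
    """A deployable model: spec + fitted selector and classifier state."""

    spec: ModelSpec
    selected_features: list[str]
    classifier: object = field(repr=False)
    cv_accuracy: float = float("nan")
    training_fingerprint: str = ""

    def predict_scores(self, table: FeatureTable) -> np.ndarray:
        """Class-1 probability per sample."""
        missing = [f for f in self.selected_features if f not in table.feature_names]
        if missing:
            raise ValueError(f"table lacks selected features {missing[:5]}")
        cols = [table.feature_names.index(f) for f in self.selected_features]
        proba = self.classifier.predict_proba(table.values[:, cols])
        return proba[:, list(self.classifier.classes_).index(1)]


def fit_model(spec: ModelSpec, table: FeatureTable, labels, seed: int = 0,
              cv_accuracy: float = float("nan")) -> TrainedModel:
    """Fit selector + classifier on the full training table."""
    X, y = _extract_xy(table, labels)
    fit_seed = derive_seed(seed, spec.model_id, "final_fit")
    k = min(spec.selector_k, X.shape[1])
    cols = SELECTORS[spec.selector_id](X, y, k, fit_seed)
    clf = CLASSIFIERS[spec.classifier_id](fit_seed)
    clf.fit(X[:, cols], y)
    import hashlib

    fingerprint = hashlib.sha256(
        np.ascontiguousarray(X).tobytes() + y.tobytes()
    ).hexdigest()[:16]
    return TrainedModel(
        spec=spec,
        selected_features=[table.feature_names[c] for c in cols],
        classifier=clf,
        cv_accuracy=cv_accuracy,
        training_fingerprint=fingerprint,
    )


def select_top_k(ranked: list[CVReport], k: int, table: FeatureTable,
                 labels, seed: int = 0) -> list[TrainedModel]:
    """Screen the top-k ranked models and refit each on the full cohort."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the {len(ranked)} ranked models")
    return [
        fit_model(r.spec, table, labels, seed=seed, cv_accuracy=r.mean_acc)
        for r in ranked[:k]
    ]
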