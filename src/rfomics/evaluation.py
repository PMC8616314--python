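"""Metrics, paired comparisons and the four evaluation studies.

Classification performance is summarized by AUC (Mann-Whitney rank
formulation, ties credited 0.5), accuracy, sensitivity (positive-class
recall; positive class = GBM) and specificity, from the thresholded
confusion table. Paired comparisons use the Wilcoxon signed-rank test
with p < 0.05 as the significance level.

The four studies:

1. VOI sweep — per (sequence, VOI) feature table, run the whole model
   zoo under stratified 5-fold CV and report the mean AUC over models
   and folds.
2. Sequence sweep — for each of the 15 modality subsets, fuse (subsets
   of >= 2, refitting the fusion inside each CV training fold) and run
   the zoo; singletons use the raw table.
3. Reader comparison — per-reader and MDT-vote metrics, compared with a
   model via paired bootstrap resampling of the test set feeding the
   Wilcoxon test.
4. Top-feature analyses — selection-frequency ranking over qualifying
   models (CV AUC above a floor) and the class-mean midpoint threshold
   analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .feature_io import FeatureTable, ModalityBundle
from .fusion import apply_feature_fusion, enumerate_sequence_combinations, fit_feature_fusion
from .utils import derive_seed

__all__ = [
    "MetricSet",
    "SweepReport",
    "FeatureFrequencyReport",
    "ThresholdReport",
    "compute_metrics",
    "paired_wilcoxon",
    "voi_sweep",
    "sequence_sweep",
    "reader_comparison",
    "top_feature_frequency",
    "class_mean_threshold_analysis",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class MetricSet:
    """AUC / ACC / SEN / SPE plus the confusion counts behind them."""

    auc: float
    acc: float
    sen: float
    spe: float
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: int = 1

    def as_dict(self) -> dict:
        return {
            "AUC": self.auc, "ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
        }


def compute_metrics(scores, labels, threshold: float = 0.5,
                    positive_class: int = 1) -> MetricSet:
    """Metrics from class-1 scores and binary labels.

    AUC is the Mann-Whitney rank statistic (ties 0.5); ACC/SEN/SPE come
    from the confusion table at ``score >= threshold``. With a single
    class present the AUC is undefined and raises; threshold metrics
    would still be computable but share this entry point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    y = (labels == positive_class).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    auc = float(roc_auc_score(y, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return MetricSet(
        auc=auc,
        acc=(tp + tn) / len(y),
        sen=tp / (tp + fn) if tp + fn else float("nan"),
        spe=tn / (tn + fp) if tn + fp else float("nan"),
        tp=tp, fp=fp, tn=tn, fn=fn,
        positive_class=positive_class,
    )


def paired_wilcoxon(x, y) -> dict:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (standard practice); if every pair is
    tied the result is flagged degenerate with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return {"statistic": float("nan"), "p_value": 1.0, "degenerate": True,
                "n_effective": 0, "significant": False}
    stat, p = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p), "degenerate": False,
            "n_effective": int(nonzero.size),
            "significant": bool(p < SIGNIFICANCE_LEVEL)}


@dataclass
class SweepReport:
    """Fold-level AUC records over a grid of conditions x models."""

    axis_name: str  # "voi" or "sequence_combination"
    records: list = field(default_factory=list)
    # each record: {"cell": str, "model": str, "fold": int, "auc": float}

    def cell_mean_auc(self) -> dict[str, float]:
        """Mean AUC over all models and folds, per grid cell."""
        sums: dict[str, list[float]] = {}
        for r in self.records:
            sums.setdefault(r["cell"], []).append(r["auc"])
        return {cell: float(np.mean(v)) for cell, v in sums.items()}

    def best_cell(self) -> str:
        means = self.cell_mean_auc()
        return max(sorted(means), key=means.get)


def voi_sweep(tables: dict, labels, zoo_config=None, folds: int = 5,
              seed: int = 0) -> SweepReport:
    """Study 1: discriminative power of each (sequence, VOI) cell.

    ``tables`` maps ``(sequence_id, voi_label)`` to a FeatureTable; for
    each cell every zoo model is evaluated by stratified k-fold CV with
    no fusion, and fold AUCs are recorded. Missing cells are simply
    absent from the report.
    """
    from .model_zoo import build_model_zoo, run_stratified_cv

    specs = build_model_zoo(zoo_config)
    report = SweepReport(axis_name="voi")
    for (seq, voi), table in sorted(tables.items()):
        cell = f"{seq}/{voi}"
        for spec in specs:
            cv = run_stratified_cv(spec, table, labels, folds=folds,
                                   seed=derive_seed(seed, "voi_sweep", cell))
            for k, auc in enumerate(cv.fold_auc):
                report.records.append(
                    {"cell": cell, "model": spec.model_id, "fold": k, "auc": auc}
                )
    return report


def sequence_sweep(bundle: ModalityBundle, labels, zoo_config=None,
                   folds: int = 5, seed: int = 0,
                   subsets=None) -> SweepReport:
    """Study 2: the 15 sequence-combination feature types.

    Singleton subsets evaluate the raw modality table through the zoo;
    subsets of two or more refit the feature fusion inside every CV
    training fold and apply it to the held-out fold, honoring the
    train/test separation at CV scale.
    """
    from .model_zoo import build_model_zoo, run_stratified_cv

    labels = np.asarray(labels, dtype=int)
    specs = build_model_zoo(zoo_config)
    if subsets is None:
        subsets = enumerate_sequence_combinations(bundle.modality_ids)
    report = SweepReport(axis_name="sequence_combination")
    for subset in subsets:
        cell = "+".join(subset)
        sub = bundle.select_modalities(list(subset))
        if len(subset) == 1:
            data: FeatureTable | ModalityBundle = sub.tables[0]
            fuse = False
        else:
            data = sub
            fuse = True
        for spec in specs:
            cv = run_stratified_cv(
                spec, data, labels, folds=folds,
                seed=derive_seed(seed, "sequence_sweep", cell),
                fuse_in_fold=fuse,
            )
            for k, auc in enumerate(cv.fold_auc):
                report.records.append(
                    {"cell": cell, "model": spec.model_id, "fold": k, "auc": auc}
                )
    return report


def _plurality_vote(votes: np.ndarray, positive_class: int = 1) -> np.ndarray:
    """Per-sample plurality over reader columns; ties go positive."""
    n_pos = (votes == positive_class).sum(axis=1)
    n_neg = votes.shape[1] - n_pos
    if np.any(n_pos == n_neg):
        warnings.warn("vote tie broken toward the positive class", stacklevel=2)
    return np.where(n_pos >= n_neg, positive_class, 1 - positive_class)


def reader_comparison(model_scores, labels, reader_predictions: dict,
                      threshold: float = 0.5, n_bootstrap: int = 2000,
                      seed: int = 0) -> dict:
    """Study 3: model vs. human readers and their MDT vote.

    ``reader_predictions`` maps reader id to per-sample hard classes
    aligned with ``labels``. Each reader and the plurality (MDT) vote
    get a MetricSet; the model is compared against each via paired
    bootstrap resampling of the test set (accuracy per replicate)
    feeding the Wilcoxon signed-rank test.
    """
    model_scores = np.asarray(model_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    readers = {}
    for rid, preds in reader_predictions.items():
        preds = np.asarray(preds, dtype=int)
        if preds.shape != labels.shape:
            raise ValueError(f"reader {rid!r} predictions misaligned")
        readers[rid] = preds

    vote_matrix = np.column_stack(list(readers.values()))
    mdt = _plurality_vote(vote_matrix)

    model_pred = (model_scores >= threshold).astype(int)
    rng = np.random.default_rng(derive_seed(seed, "reader_bootstrap"))
    idx = rng.integers(0, n, size=(n_bootstrap, n))

    def _boot_acc(pred):
        return (pred[idx] == labels[idx]).mean(axis=1)

    model_boot = _boot_acc(model_pred)
    out = {"model": compute_metrics(model_scores, labels, threshold),
           "readers": {}, "mdt": None, "comparisons": {}}
    for rid, preds in readers.items():
        out["readers"][rid] = compute_metrics(preds.astype(float), labels, threshold)
        cmp = paired_wilcoxon(model_boot, _boot_acc(preds))
        out["comparisons"][rid] = cmp
    out["mdt"] = compute_metrics(mdt.astype(float), labels, threshold)
    out["comparisons"]["MDT"] = paired_wilcoxon(model_boot, _boot_acc(mdt))
    return out


def append_covariates(table: FeatureTable, covariates: dict) -> FeatureTable:
    """Append clinical covariate columns (e.g. age, lesion location) to a
    fused feature table so they enter feature selection alongside the
    radiomics features; supports 'radiomics', 'age + radiomics', etc. run
    modes."""
    names = list(table.feature_names)
    values = [table.values]
    for name, col in covariates.items():
        col = np.asarray(col, dtype=float)
        if col.shape != (table.n_samples,):
            raise ValueError(f"covariate {name!r} must have one value per sample")
        if name in names:
            raise ValueError(f"covariate {name!r} collides with a feature name")
        names.append(name)
        values.append(col[:, None])
    return FeatureTable(
        modality_id=table.modality_id,
        sample_ids=list(table.sample_ids),
        feature_names=names,
        values=np.hstack(values),
        labels=table.labels,
    )


def null_zoo_calibration(n_per_class: int = 250, n_features: int = 20,
                         n_replicates: int = 20, zoo_config=None,
                         folds: int = 5, seed: int = 0) -> dict:
    """Grand-mean CV AUC of the zoo on label-permuted data.

    Draws pure-noise feature tables (labels independent of features),
    runs every zoo model under stratified CV and averages the fold AUCs
    over models and replicates. A well-calibrated pipeline — feature
    selection strictly inside folds — lands near 0.5; leakage inflates
    it.
    """
    from .feature_io import FeatureTable
    from .model_zoo import build_model_zoo, run_stratified_cv

    specs = build_model_zoo(zoo_config)
    aucs = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(derive_seed(seed, "null_calibration", rep))
        n = 2 * n_per_class
        values = rng.standard_normal((n, n_features))
        labels = rng.permutation(np.repeat([0, 1], n_per_class))
        table = FeatureTable("null", [f"s{i}" for i in range(n)],
                             [f"f{j}" for j in range(n_features)], values)
        for spec in specs:
            cv = run_stratified_cv(spec, table, labels, folds=folds,
                                   seed=derive_seed(seed, "null_cv", rep))
            aucs.extend(cv.fold_auc)
    return {"grand_mean_auc": float(np.mean(aucs)),
            "n_replicates": n_replicates,
            "n_models": len(specs),
            "n_per_class": n_per_class}


@dataclass
class FeatureFrequencyReport:
    """Selection counts over qualifying model-fold fits."""

    counts: dict[str, int]
    auc_floor: float
    n_qualifying: int

    def ranked(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def top(self, k: int = 10) -> list[str]:
        return [name for name, _ in self.ranked()[:k]]


def top_feature_frequency(reports, auc_floor: float = 0.8) -> FeatureFrequencyReport:
    """Study 4a: rank features by selection frequency.

    Only models with mean CV AUC strictly above ``auc_floor`` qualify;
    within a qualifying model every fold's selected feature set counts.
    """
    counts: dict[str, int] = {}
    n_qual = 0
    for report in reports:
        if report.mean_auc > auc_floor:
            n_qual += 1
            for fold_features in report.fold_selected_features:
                for f in fold_features:
                    counts[f] = counts.get(f, 0) + 1
    return FeatureFrequencyReport(counts=counts, auc_floor=auc_floor,
                                  n_qualifying=n_qual)


@dataclass
class ThresholdReport:
    """Class-mean midpoint threshold analysis per feature."""

    rows: list
    # each row: {"feature", "mean_pos", "mean_neg", "M",
    #            "pos_below_pct", "pos_above_pct",
    #            "neg_below_pct", "neg_above_pct"}


def class_mean_threshold_analysis(table: FeatureTable, labels=None,
                                  features=None,
                                  positive_class: int = 1) -> ThresholdReport:
    """Study 4b: per feature, threshold at the midpoint of class means.

    M = (mean of the positive class + mean of the negative class) / 2;
    reports the percentage of each class below and above M. Values
    exactly equal to M count as below.
    """
    if labels is None:
        labels = table.labels
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required")
    if features is None:
        features = table.feature_names
    pos = labels == positive_class
    neg = ~pos
    rows = []
    for f in features:
        j = table.feature_names.index(f)
        v = table.values[:, j]
        mu_pos, mu_neg = v[pos].mean(), v[neg].mean()
        M = 0.5 * (mu_pos + mu_neg)
        rows.append({
            "feature": f,
            "mean_pos": float(mu_pos),
            "mean_neg": float(mu_neg),
            "M": float(M),
            "pos_below_pct": float(100 * (v[pos] <= M).mean()),
            "pos_above_pct": float(100 * (v[pos] > M).mean()),
            "neg_below_pct": float(100 * (v[neg] <= M).mean()),
            "neg_above_pct": float(100 * (v[neg] > M).mean()),
        })
    return ThresholdReport(rows=rows)
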