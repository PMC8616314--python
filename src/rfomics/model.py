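"""Top-level modelling interface: RadioFusionOmics model and results.

`RadioFusionOmics` is constructed from a labelled multi-modality
training bundle; `fit()` runs the full two-level pipeline —

1. feature-level fusion (between-class scatter whitening per feature),
2. the 15-model zoo under stratified 5-fold CV,
3. screening of the top 3 models,
4. the accuracy-weighted consensus —

and returns an :class:`RFOResults` object carrying the fitted fusion
transform, every model's CV record (mean and SD of AUC/ACC/SEN/SPE),
the ranking, the consensus weights, and prediction/evaluation methods
for held-out bundles.

Example
-------
>>> from rfomics import RadioFusionOmics, synthetic
>>> tr_b, tr_y, te_b, te_y = synthetic.default_study_scenario(seed=0)
>>> res = RadioFusionOmics(tr_b, tr_y, modalities=["T1WI", "T2_FLAIR"]).fit()
>>> print(res.summary())                       # doctest: +SKIP
>>> res.evaluate(te_b, te_y).as_dict()         # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import ConsensusModel
from .evaluation import MetricSet, compute_metrics
from .feature_io import FeatureTable, ModalityBundle
from .fusion import FusionTransform, apply_feature_fusion, fit_feature_fusion
from .model_zoo import (
    CVReport,
    build_model_zoo,
    rank_models,
    run_stratified_cv,
    select_top_k,
)
from .utils import derive_seed

__all__ = ["RadioFusionOmics", "RFOResults"]


class RadioFusionOmics:
    """Two-level radiomics fusion model for a binary discrimination task.

    Parameters
    ----------
    bundle
        Training :class:`ModalityBundle` (p aligned modality tables).
        A single-modality bundle skips feature fusion and models the
        raw table.
    labels
        Binary class per training sample (positive class = 1 = GBM by
        convention). Defaults to the labels carried by the bundle.
    modalities
        Modality subset to fuse (default: all modalities in the bundle).
    zoo_config
        Model-zoo configuration (``selectors``, ``classifiers``,
        ``selector_k``); defaults give the 5 x 3 = 15 grid with 10
        selected features per model.
    top_k
        Number of screened models entering the consensus (default 3).
    folds
        Stratified CV folds (default 5).
    """

    def __init__(self, bundle: ModalityBundle, labels=None, *,
                 modalities=None, zoo_config: dict | None = None,
                 top_k: int = 3, folds: int = 5, fusion_tol: float = 1e-10):
        if modalities is not None:
            bundle = bundle.select_modalities(list(modalities))
        self.bundle = bundle
        labels = bundle.labels if labels is None else np.asarray(labels, int)
        if labels is None:
            raise ValueError("training labels are required")
        self.labels = np.asarray(labels, dtype=int)
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present for fitting")
        self.zoo_config = dict(zoo_config or {})
        self.top_k = top_k
        self.folds = folds
        self.fusion_tol = fusion_tol

    @classmethod
    def from_tables(cls, tables: list[FeatureTable], labels=None, **kwargs):
        return cls(ModalityBundle(tables), labels, **kwargs)

    def fit(self, seed: int = 0) -> "RFOResults":
        """Run fusion, CV screening and consensus; return results."""
        fuse = self.bundle.n_modalities >= 2
        if fuse:
            transform, fused = fit_feature_fusion(
                self.bundle, self.labels, tol=self.fusion_tol
            )
        else:
            transform, fused = None, self.bundle.tables[0]

        specs = build_model_zoo(self.zoo_config)
        reports = []
        for spec in specs:
            # CV on the training cohort; fusion refit inside each fold
            # when fusing, so held-out folds never shape the transform.
            data = self.bundle if fuse else fused
            reports.append(
                run_stratified_cv(
                    spec, data, self.labels, folds=self.folds,
                    seed=derive_seed(seed, "zoo_cv"), fuse_in_fold=fuse,
                )
            )
        ranked = rank_models(reports)
        members = select_top_k(ranked, self.top_k, fused, self.labels,
                               seed=derive_seed(seed, "final_fit"))
        consensus = ConsensusModel.from_members(members)
        return RFOResults(
            model=self,
            transform=transform,
            fused_training_table=fused,
            cv_reports=reports,
            ranking=ranked,
            consensus=consensus,
            seed=seed,
        )


@dataclass
class RFOResults:
    """Fitted pipeline state plus diagnostics."""

    model: RadioFusionOmics
    transform: FusionTransform | None
    fused_training_table: FeatureTable
    cv_reports: list[CVReport]
    ranking: list[CVReport]
    consensus: ConsensusModel
    seed: int = 0

    # -- prediction -------------------------------------------------------

    def _fuse(self, bundle: ModalityBundle) -> FeatureTable:
        if self.transform is None:
            if bundle.n_modalities != 1:
                raise ValueError("model was fitted on a single modality")
            return bundle.tables[0]
        sub = bundle.select_modalities(self.transform.modality_order)
        return apply_feature_fusion(self.transform, sub)

    def predict(self, bundle: ModalityBundle):
        """(consensus scores, hard classes) for a held-out bundle."""
        return self.consensus.predict(self._fuse(bundle))

    def predict_majority(self, bundle: ModalityBundle) -> np.ndarray:
        """Majority-vote baseline over the same member models."""
        return self.consensus.predict_majority(self._fuse(bundle))

    def member_scores(self, bundle: ModalityBundle) -> np.ndarray:
        return self.consensus.member_scores(self._fuse(bundle))

    def evaluate(self, bundle: ModalityBundle, labels=None) -> MetricSet:
        """Consensus AUC/ACC/SEN/SPE on a labelled held-out bundle."""
        labels = bundle.labels if labels is None else labels
        if labels is None:
            raise ValueError("labels required for evaluation")
        scores, _ = self.predict(bundle)
        return compute_metrics(scores, labels, self.consensus.threshold)

    # -- diagnostics ------------------------------------------------------

    @property
    def weights(self) -> np.ndarray:
        return self.consensus.weights

    def cv_table(self) -> pd.DataFrame:
        """Per-model CV summary, in ranked order."""
        return pd.DataFrame([r.summary() for r in self.ranking])

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = []
        p = self.model.bundle.n_modalities
        lines.append("RadioFusionOmics fit")
        lines.append("=" * 64)
        lines.append(f"modalities fused : {', '.join(self.model.bundle.modality_ids)}"
                     f" (p={p})")
        lines.append(f"training samples : {self.model.bundle.n_samples} "
                     f"(positive={int((self.model.labels == 1).sum())}, "
                     f"negative={int((self.model.labels == 0).sum())})")
        lines.append(f"features         : {len(self.fused_training_table.feature_names)}")
        if self.transform is not None:
            lines.append(f"degenerate feats : {len(self.transform.degenerate_features)}")
        lines.append(f"models evaluated : {len(self.cv_reports)} "
                     f"({self.model.folds}-fold stratified CV)")
        lines.append("")
        df = self.cv_table()
        lines.append(df.to_string(
            index=False,
            float_format=lambda v: f"{v:.3f}",
            columns=["model", "mean_auc", "sd_auc", "mean_acc", "sd_acc"],
        ))
        lines.append("")
        lines.append("consensus (accuracy-weighted soft vote)")
        for m, w in zip(self.consensus.members, self.consensus.weights):
            lines.append(f"  {m.spec.model_id:<28s} weight={w:.4f} "
                         f"(cv acc={m.cv_accuracy:.3f})")
        return "\n".join(lines)

    def plot_cv(self, ax=None):
        """Boxplot of fold AUCs per model (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        data = [r.fold_auc for r in self.ranking]
        ax.boxplot(data, labels=[r.spec.model_id for r in self.ranking])
        ax.set_ylabel("fold AUC")
        ax.tick_params(axis="x", rotation=90)
        return ax
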