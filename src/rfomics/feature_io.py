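"""Reading, validating, standardizing and splitting radiomics feature tables.

One :class:`FeatureTable` holds the feature matrix of a single MRI
sequence (modality): n samples by m named features, with sample ids and
optional binary class labels (positive class = GBM = 1 by convention,
configurable downstream). A :class:`ModalityBundle` aligns several such
tables — identical sample ids in identical order, identical feature
names — which is the unit the feature-fusion stage consumes.

Standardization is per (modality, feature) z-scoring with statistics
learned on the training subset only; the fitted :class:`Standardizer`
travels with the fusion transform so held-out data are transformed with
zero test-time fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import FeatureRegistry

__all__ = [
    "FeatureTable",
    "ModalityBundle",
    "Standardizer",
    "CohortSplit",
    "read_feature_table",
    "write_feature_table",
    "validate_against_registry",
    "fit_standardizer",
    "apply_standardizer",
    "split_cohort",
]

#: §2.5.3 cohort sizes 121/62/61 out of 244 as fractions.
DEFAULT_SPLIT_FRACTIONS = (121 / 244, 62 / 244, 61 / 244)


@dataclass
class FeatureTable:
    """Feature matrix of one modality: n samples x m features."""

    modality_id: str
    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n, m) float
    labels: np.ndarray | None = None  # (n,) in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length does not match values")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_names)) != m:
            raise ValueError("duplicate feature names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain NaN/inf")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match values")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary {0, 1}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids: list[str]) -> "FeatureTable":
        """Row subset in the given id order."""
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        rows = [index[sid] for sid in sample_ids]
        return FeatureTable(
            modality_id=self.modality_id,
            sample_ids=list(sample_ids),
            feature_names=list(self.feature_names),
            values=self.values[rows],
            labels=None if self.labels is None else self.labels[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "sample_id", self.sample_ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df


@dataclass
class ModalityBundle:
    """Aligned feature tables, one per modality (p in {1, .., 4})."""

    tables: list[FeatureTable]

    def __post_init__(self) -> None:
        if not 1 <= len(self.tables) <= 4:
            raise ValueError("bundle must hold 1-4 modality tables")
        ids = [t.modality_id for t in self.tables]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate modality ids in bundle")
        ref = self.tables[0]
        for t in self.tables[1:]:
            if t.sample_ids != ref.sample_ids:
                raise ValueError("bundle tables must share sample_ids in order")
            if t.feature_names != ref.feature_names:
                raise ValueError("bundle tables must share feature_names")

    @property
    def modality_ids(self) -> list[str]:
        return [t.modality_id for t in self.tables]

    @property
    def sample_ids(self) -> list[str]:
        return self.tables[0].sample_ids

    @property
    def feature_names(self) -> list[str]:
        return self.tables[0].feature_names

    @property
    def n_modalities(self) -> int:
        return len(self.tables)

    @property
    def n_samples(self) -> int:
        return self.tables[0].n_samples

    @property
    def labels(self) -> np.ndarray | None:
        return self.tables[0].labels

    def table(self, modality_id: str) -> FeatureTable:
        for t in self.tables:
            if t.modality_id == modality_id:
                return t
        raise KeyError(f"no modality {modality_id!r} in bundle")

    def select_modalities(self, modality_ids: list[str]) -> "ModalityBundle":
        return ModalityBundle([self.table(mid) for mid in modality_ids])

    def subset(self, sample_ids: list[str]) -> "ModalityBundle":
        return ModalityBundle([t.subset(sample_ids) for t in self.tables])


def read_feature_table(
    path: str | Path,
    modality_id: str,
    *,
    id_column: str = "sample_id",
    label_column: str = "label",
    require_labels: bool = False,
) -> FeatureTable:
    """Read one modality's feature CSV.

    Layout: first column ``sample_id``, optional ``label`` column in
    {0, 1}, remaining columns numeric features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={id_column: str})
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing id column {id_column!r}")
    sample_ids = df[id_column].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    labels = None
    if label_column in df.columns:
        if df[label_column].isna().any():
            raise ValueError(f"{path}: missing label values")
        labels = df[label_column].to_numpy()
    elif require_labels:
        raise ValueError(f"{path}: labels requested but column {label_column!r} absent")
    feat_cols = [c for c in df.columns if c not in (id_column, label_column)]
    if not feat_cols:
        raise ValueError(f"{path}: no feature columns")
    block = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    if block.isna().any().any():
        bad = block.isna().stack()
        row, col = bad[bad].index[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at row {row!r}, column {col!r}"
        )
    return FeatureTable(
        modality_id=modality_id,
        sample_ids=sample_ids,
        feature_names=feat_cols,
        values=block.to_numpy(dtype=float),
        labels=labels,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table to the CSV dialect `read_feature_table` ingests."""
    table.to_frame().to_csv(path, index=False)


def validate_against_registry(
    table: FeatureTable, registry: FeatureRegistry, strict: bool = False
) -> dict:
    """Compare a table's feature names with the registry.

    Returns ``{"missing": [...], "extra": [...], "ok": bool}``; in
    strict mode any mismatch raises.
    """
    expected = registry.feature_names
    have = set(table.feature_names)
    missing = [f for f in expected if f not in have]
    extra = sorted(have - set(expected))
    report = {"missing": missing, "extra": extra, "ok": not missing and not extra}
    if strict and not report["ok"]:
        raise ValueError(
            f"feature set mismatch: missing={missing[:10]} extra={extra[:10]}"
        )
    return report


@dataclass
class Standardizer:
    """Per-(modality, feature) location/scale, fitted on training ids only."""

    modality_ids: list[str]
    feature_names: list[str]
    location: np.ndarray  # (p, m)
    scale: np.ndarray  # (p, m), strictly positive
    zero_variance: np.ndarray = field(default=None)  # (p, m) bool flags

    def __post_init__(self) -> None:
        if self.zero_variance is None:
            self.zero_variance = np.zeros_like(self.scale, dtype=bool)
        if np.any(self.scale <= 0):
            raise ValueError("standardizer scale must be positive")


def fit_standardizer(bundle: ModalityBundle, sample_subset=None) -> Standardizer:
    """Fit per-(modality, feature) mean/SD on a subset of sample ids.

    Zero-variance features are flagged and kept with scale 1 so registry
    alignment across modalities is preserved.
    """
    if sample_subset is None:
        sample_subset = bundle.sample_ids
    sample_subset = list(sample_subset)
    if len(sample_subset) < 2:
        raise ValueError("standardizer needs at least 2 training samples")
    sub = bundle.subset(sample_subset)
    p, m = sub.n_modalities, len(sub.feature_names)
    location = np.empty((p, m))
    scale = np.empty((p, m))
    flagged = np.zeros((p, m), dtype=bool)
    for k, t in enumerate(sub.tables):
        location[k] = t.values.mean(axis=0)
        sd = t.values.std(axis=0, ddof=1)
        zero = sd <= 0
        if zero.any():
            names = [t.feature_names[j] for j in np.flatnonzero(zero)[:5]]
            warnings.warn(
                f"modality {t.modality_id!r}: zero-variance features {names}"
                " retained with scale 1",
                stacklevel=2,
            )
        flagged[k] = zero
        scale[k] = np.where(zero, 1.0, sd)
    return Standardizer(
        modality_ids=sub.modality_ids,
        feature_names=list(sub.feature_names),
        location=location,
        scale=scale,
        zero_variance=flagged,
    )


def apply_standardizer(std: Standardizer, bundle: ModalityBundle) -> ModalityBundle:
    """z-score a bundle with previously fitted statistics."""
    if bundle.modality_ids != std.modality_ids:
        raise ValueError(
            f"modality mismatch: bundle {bundle.modality_ids} vs "
            f"standardizer {std.modality_ids}"
        )
    if bundle.feature_names != std.feature_names:
        raise ValueError("feature names do not match the fitted standardizer")
    tables = []
    for k, t in enumerate(bundle.tables):
        tables.append(
            FeatureTable(
                modality_id=t.modality_id,
                sample_ids=list(t.sample_ids),
                feature_names=list(t.feature_names),
                values=(t.values - std.location[k]) / std.scale[k],
                labels=t.labels,
            )
        )
    return ModalityBundle(tables)


@dataclass
class CohortSplit:
    """Disjoint named sample-id partitions."""

    training: list[str]
    testing_1: list[str]
    testing_2: list[str]

    def __post_init__(self) -> None:
        parts = [set(self.training), set(self.testing_1), set(self.testing_2)]
        total = sum(len(s) for s in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split partitions must be pairwise disjoint")

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "training": list(self.training),
            "testing_1": list(self.testing_1),
            "testing_2": list(self.testing_2),
        }


def split_cohort(
    sample_ids,
    labels,
    fractions: tuple[float, float, float] = DEFAULT_SPLIT_FRACTIONS,
    seed: int = 0,
) -> CohortSplit:
    """Label-stratified three-way split, deterministic under seed.

    Within each class, ids are shuffled and cut at the cumulative
    fraction boundaries (largest-remainder rounding so partition sizes
    add up exactly), so class proportions per partition match the global
    proportion to within one sample.
    """
    sample_ids = list(sample_ids)
    labels = np.asarray(labels, dtype=int)
    if len(sample_ids) != len(labels):
        raise ValueError("sample_ids and labels length mismatch")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[str]] = [[], [], []]
    for cls in np.unique(labels):
        ids = [sid for sid, y in zip(sample_ids, labels) if y == cls]
        rng.shuffle(ids)
        n = len(ids)
        raw = np.asarray(fractions) * n
        sizes = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
            sizes[i] += 1
        cut = np.concatenate(([0], np.cumsum(sizes)))
        for i in range(3):
            parts[i].extend(ids[cut[i]: cut[i + 1]])
    for i, name in enumerate(("training", "testing_1", "testing_2")):
        if fractions[i] > 0:
            got = {labels[sample_ids.index(s)] for s in parts[i]}
            if len(got) < len(np.unique(labels)):
                warnings.warn(f"partition {name!r} misses a class", stacklevel=2)
    return CohortSplit(training=parts[0], testing_1=parts[1], testing_2=parts[2])
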