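"""Synthetic two-class multi-modality feature tables and toy masks.

The clinical cohort behind the method is not publicly deposited, so
every stage of the pipeline is exercised on simulated data with known
ground truth. The generative model is deliberately simple enough to
admit closed-form oracles: for sample with class y in {0, 1}, feature
j, modality k,

    value_jk = delta_jk * y + eps_jk,

with the noise eps jointly normal across modalities (unit variance,
equicorrelation rho). Under this model a single feature with effect
size delta separates the classes with AUC = Phi(delta / sqrt(2)), which
calibrates the generator against theory.

Complementarity mode places the informative features of different
modalities on disjoint feature sets, the regime in which cross-modality
fusion genuinely adds information; shared mode makes modalities
redundant instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feature_io import FeatureTable, ModalityBundle
from .registry import default_registry
from .utils import derive_seed
from .voi_masks import VoxelMask

__all__ = [
    "SimulationConfig",
    "simulate_multimodal_features",
    "default_study_scenario",
    "simulate_toy_masks",
]

#: Default modality names mirror the four conventional MR sequences.
DEFAULT_MODALITIES = ("T1WI", "CE_T1WI", "T2WI", "T2_FLAIR")


@dataclass
class SimulationConfig:
    """Knobs of the Gaussian two-class generator.

    ``effect_sizes`` maps modality id -> per-feature effect vector (or
    a scalar applied to that modality's informative features);
    ``informative_fraction`` controls how many features per modality
    carry signal; ``complementarity`` chooses whether the informative
    sets of different modalities are disjoint or shared.
    """

    n_per_class: int = 60
    n_modalities: int = 2
    n_features: int = 20
    effect_size: float = 0.8
    informative_fraction: float = 0.3
    noise_correlation: float = 0.0
    complementarity: str = "disjoint"  # or "shared"
    modality_ids: tuple = ()
    seed: int = 0
    effect_sizes: dict = field(default_factory=dict)  # optional per-modality override

    def __post_init__(self) -> None:
        if self.complementarity not in ("disjoint", "shared"):
            raise ValueError("complementarity must be 'disjoint' or 'shared'")
        if not self.modality_ids:
            self.modality_ids = DEFAULT_MODALITIES[: self.n_modalities]
        if len(self.modality_ids) != self.n_modalities:
            raise ValueError("modality_ids length must equal n_modalities")
        p = self.n_modalities
        # equicorrelated covariance is PSD iff rho >= -1/(p-1)
        lo = -1.0 / (p - 1) if p > 1 else 0.0
        if not (lo - 1e-12 <= self.noise_correlation <= 1.0):
            raise ValueError(
                f"noise_correlation must lie in [{lo:.3f}, 1] for p={p}"
            )


def _effect_matrix(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(p, m) matrix of per-(modality, feature) effect sizes delta."""
    p, m = config.n_modalities, config.n_features
    delta = np.zeros((p, m))
    n_inf = max(1, int(round(config.informative_fraction * m)))
    if config.complementarity == "shared":
        idx = np.arange(n_inf)
        for k, mid in enumerate(config.modality_ids):
            delta[k, idx] = config.effect_sizes.get(mid, config.effect_size)
    else:  # disjoint blocks, wrapping if p * n_inf > m
        for k, mid in enumerate(config.modality_ids):
            idx = (np.arange(n_inf) + k * n_inf) % m
            delta[k, idx] = config.effect_sizes.get(mid, config.effect_size)
    return delta


def simulate_multimodal_features(
    config: SimulationConfig,
) -> tuple[ModalityBundle, np.ndarray]:
    """Draw a labelled multi-modality bundle from the Gaussian model.

    Noise is jointly normal across the p modalities with unit variance
    and equicorrelation rho; the class shifts the mean of informative
    features by delta standard deviations. Bit-identical under a fixed
    seed.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "simulate_features"))
    p, m = config.n_modalities, config.n_features
    n = 2 * config.n_per_class
    labels = np.repeat([0, 1], config.n_per_class)

    rho = config.noise_correlation
    cov = np.full((p, p), rho, dtype=float)
    np.fill_diagonal(cov, 1.0)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance is not positive semi-definite") from exc

    delta = _effect_matrix(config, rng)
    # eps: (p, n, m) correlated across the first axis
    white = rng.standard_normal(size=(p, n, m))
    eps = np.einsum("qp,pnm->qnm", chol, white)
    values = delta[:, None, :] * labels[None, :, None] + eps

    sample_ids = [f"s{i:04d}" for i in range(n)]
    feature_names = [f"f{j:03d}" for j in range(m)]
    tables = [
        FeatureTable(
            modality_id=mid,
            sample_ids=sample_ids,
            feature_names=feature_names,
            values=values[k],
            labels=labels,
        )
        for k, mid in enumerate(config.modality_ids)
    ]
    return ModalityBundle(tables), labels


#: Cohort shape of the study: 121 training (61 positive / 60 negative)
#: and 62 held-out samples (33 / 29), four MR sequences, 109 features.
STUDY_TRAIN_POS, STUDY_TRAIN_NEG = 61, 60
STUDY_TEST_POS, STUDY_TEST_NEG = 33, 29


def _study_bundle(n_pos: int, n_neg: int, seed: int, id_prefix: str) -> tuple:
    registry = default_registry()
    m = len(registry)
    rng = np.random.default_rng(seed)
    p = 4
    modality_ids = DEFAULT_MODALITIES
    # two strongly informative, complementary sequences (T1WI, T2_FLAIR)
    # with disjoint informative feature blocks; the other two weak.
    n_inf = 33  # ~0.3 of the 109 registry features
    delta = np.zeros((p, m))
    delta[0, :n_inf] = 0.8                      # T1WI block
    delta[3, n_inf: 2 * n_inf] = 0.8            # T2_FLAIR block (disjoint)
    delta[1, 2 * n_inf: 2 * n_inf + 11] = 0.3   # CE_T1WI, weak
    delta[2, 2 * n_inf + 11: 2 * n_inf + 22] = 0.3  # T2WI, weak

    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    order = rng.permutation(n)
    labels = labels[order]
    cov = np.eye(p)
    eps = rng.standard_normal(size=(p, n, m))
    values = delta[:, None, :] * labels[None, :, None] + eps
    sample_ids = [f"{id_prefix}{i:04d}" for i in range(n)]
    tables = [
        FeatureTable(
            modality_id=mid,
            sample_ids=sample_ids,
            feature_names=registry.feature_names,
            values=values[k],
            labels=labels,
        )
        for k, mid in enumerate(modality_ids)
    ]
    return ModalityBundle(tables), labels


def default_study_scenario(seed: int = 0):
    """The fixed synthetic stand-in for the study cohorts.

    Returns ``(train_bundle, train_labels, test_bundle, test_labels)``:
    121 training samples (61 positive / 60 negative) and a 62-sample
    held-out cohort (33 / 29), four modalities, the 109-feature
    registry, complementary informative blocks on T1WI and T2_FLAIR.
    """
    train = _study_bundle(STUDY_TRAIN_POS, STUDY_TRAIN_NEG,
                          derive_seed(seed, "study", "train"), "tr")
    test = _study_bundle(STUDY_TEST_POS, STUDY_TEST_NEG,
                         derive_seed(seed, "study", "test"), "te")
    return train[0], train[1], test[0], test[1]


def simulate_toy_masks(shape=(24, 24, 24), seed: int = 0):
    """Three disjoint toy VOIs with the core / rim / ring topology.

    nET is a central ball, ET the spherical shell around it, pTE an
    outer ring — mimicking necrotic core, enhancing tumour and
    peritumoral edema. Deterministic under seed (the centre jitters
    within the grid).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError("mask shape must be 3-D with every extent >= 8")
    rng = np.random.default_rng(derive_seed(seed, "toy_masks"))
    half = min(shape) / 2
    centre = np.array(shape) / 2 + rng.uniform(-1, 1, size=3)
    grid = np.indices(shape).reshape(3, -1).T + 0.5
    r = np.linalg.norm(grid - centre, axis=1).reshape(shape)
    r_core = 0.25 * half
    r_rim = 0.55 * half
    r_ring = 0.85 * half
    net = VoxelMask(r <= r_core, label="nET")
    et = VoxelMask((r > r_core) & (r <= r_rim), label="ET")
    pte = VoxelMask((r > r_rim) & (r <= r_ring), label="pTE")
    return net, et, pte
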