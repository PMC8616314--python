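"""Binary 3-D mask utilities for the VOI workflow.

The tumour is delineated as three base volumes of interest — the
non-enhanced tumour core (nET), the enhancing tumour (ET) and the
peritumoral edema (pTE). Two readers' delineations are reconciled by a
Dice-conformity rule (voxelwise intersection when Dice > 0.9, otherwise
routed back for review), and morphological unions of the base VOIs give
seven VOI types in total.

Masks are read and written as NIfTI; combining masks of different grid
shapes is an error — no implicit resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelMask",
    "NeedsReview",
    "dice_coefficient",
    "consensus_mask",
    "mask_union",
    "enumerate_vois",
    "read_mask",
    "write_mask",
    "BASE_VOI_LABELS",
]

BASE_VOI_LABELS = ("nET", "ET", "pTE")

#: Reconciled delineations require Dice strictly greater than this.
DICE_CONSENSUS_THRESHOLD = 0.9


@dataclass
class VoxelMask:
    """A binary occupancy grid with an optional VOI label."""

    voxels: np.ndarray  # 3-D bool
    label: str = ""
    spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError("mask must be 3-D")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask must be strictly binary")
        self.voxels = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def volume(self) -> int:
        return int(self.voxels.sum())


def _check_shapes(*masks: VoxelMask) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"mask shape mismatch: {sorted(shapes)}")


def dice_coefficient(a: VoxelMask, b: VoxelMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|).

    Two empty masks are defined as perfectly conformant (1.0), with a
    warning — the degenerate case of two readers both delineating
    nothing.
    """
    _check_shapes(a, b)
    denom = a.volume + b.volume
    if denom == 0:
        warnings.warn("Dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / denom


@dataclass
class NeedsReview:
    """Outcome when two delineations are not conformant enough."""

    dice: float
    threshold: float

    def __bool__(self) -> bool:  # a review signal is never a usable mask
        return False


def consensus_mask(
    a: VoxelMask, b: VoxelMask, threshold: float = DICE_CONSENSUS_THRESHOLD
) -> VoxelMask | NeedsReview:
    """Reconcile two delineations of the same VOI.

    If Dice is strictly greater than ``threshold`` the voxelwise
    intersection is the consensus; otherwise a :class:`NeedsReview`
    signal carrying the Dice value is returned (boundary equality
    routes to review).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    d = dice_coefficient(a, b)
    if d > threshold:
        return VoxelMask(
            np.logical_and(a.voxels, b.voxels),
            label=a.label or b.label,
            spacing=a.spacing,
        )
    return NeedsReview(dice=d, threshold=threshold)


def _canonical_label(labels: list[str]) -> str:
    order = {lab: i for i, lab in enumerate(BASE_VOI_LABELS)}
    parts: list[str] = []
    for lab in labels:
        for piece in lab.split("+"):
            if piece and piece not in parts:
                parts.append(piece)
    parts.sort(key=lambda x: order.get(x, len(order)))
    return "+".join(parts)


def mask_union(masks: list[VoxelMask]) -> VoxelMask:
    """Voxelwise OR; the label concatenates the inputs' labels in the
    canonical nET, ET, pTE order."""
    if not masks:
        raise ValueError("mask_union needs at least one mask")
    _check_shapes(*masks)
    out = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        out |= m.voxels
    return VoxelMask(out, label=_canonical_label([m.label for m in masks]),
                     spacing=masks[0].spacing)


def enumerate_vois(base_labels=BASE_VOI_LABELS) -> list[str]:
    """The seven VOI types: 3 singletons, 3 pairwise unions, 1 triple."""
    if tuple(base_labels) != BASE_VOI_LABELS:
        raise ValueError(f"base labels must be {BASE_VOI_LABELS}")
    a, b, c = base_labels
    return [a, b, c, f"{a}+{b}", f"{a}+{c}", f"{b}+{c}", f"{a}+{b}+{c}"]


def read_mask(path: str | Path, label: str = "") -> VoxelMask:
    """Load a binary NIfTI mask (any non-zero voxel counts as set)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelMask(data != 0, label=label, spacing=spacing)


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    affine = np.eye(4)
    if mask.spacing is not None:
        affine[0, 0], affine[1, 1], affine[2, 2] = mask.spacing
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))
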