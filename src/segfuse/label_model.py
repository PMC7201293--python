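"""Segmentation data model and the BraTS label convention.

A multi-class brain-tumor segmentation is a 3-D integer label volume on a
voxel grid with an affine voxel-to-world transform.  The BraTS convention
uses label 1 for the necrotic / non-enhancing tumor core, 2 for peritumoral
edema and 4 for enhancing tumor (3 is deliberately unused).  Composite
regions are nested: enhancing tumor (ET, {4}) ⊂ tumor core (TC, {1, 4}) ⊂
whole tumor (WT, {1, 2, 4}).

Fusion operates class-wise: each label (or region) is binarized into a
:class:`BinaryMask`, the binary problems are fused independently, and the
per-label results are recombined into one multi-class volume by
:func:`assemble` using a precedence order in which later labels overwrite
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import LabelError, ShapeMismatchError, ValidationError

#: Tumor labels of the BraTS convention (1 necrosis, 2 edema, 4 enhancing).
BRATS_LABELS: tuple[int, ...] = (1, 2, 4)

#: Default precedence for recombination: edema, overwritten by necrosis,
#: overwritten by enhancing tumor — mirrors the nested tumor hierarchy.
DEFAULT_PRECEDENCE: tuple[int, ...] = (2, 1, 4)

#: Default tolerance for affine agreement between candidates (max absolute
#: elementwise difference, in mm-scale matrix entries).
AFFINE_ATOL: float = 1e-3


@dataclass(frozen=True)
class RegionDefinition:
    """A named composite tumor region: a set of member labels."""

    name: str
    member_labels: frozenset[int]

    def __post_init__(self) -> None:
        if not self.member_labels:
            raise ValidationError("a region must contain at least one label")


WHOLE_TUMOR = RegionDefinition("whole_tumor", frozenset({1, 2, 4}))
TUMOR_CORE = RegionDefinition("tumor_core", frozenset({1, 4}))
ENHANCING_TUMOR = RegionDefinition("enhancing_tumor", frozenset({4}))

#: Region lookup by canonical name (and common short aliases).
REGIONS: dict[str, RegionDefinition] = {
    "whole_tumor": WHOLE_TUMOR,
    "tumor_core": TUMOR_CORE,
    "enhancing_tumor": ENHANCING_TUMOR,
    "wt": WHOLE_TUMOR,
    "tc": TUMOR_CORE,
    "et": ENHANCING_TUMOR,
}


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class MultiClassSegmentation:
    """3-D integer label volume plus spatial metadata.

    Parameters
    ----------
    voxels
        3-D array of non-negative integer labels.
    affine
        4x4 matrix mapping voxel indices to world coordinates (mm).
    label_set
        The permitted positive labels; every voxel must be 0 or a member.
    """

    voxels: np.ndarray
    affine: np.ndarray
    label_set: frozenset[int] = field(default_factory=lambda: frozenset(BRATS_LABELS))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"segmentation must be 3-D, got {self.voxels.ndim} dimensions"
            )
        if min(self.voxels.shape) < 1:
            raise ValidationError("all spatial dimensions must be >= 1")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValidationError(
                f"voxel dtype must be integer, got {self.voxels.dtype}"
            )
        self.affine = _check_affine(self.affine)
        self.label_set = frozenset(int(v) for v in self.label_set)
        if any(v <= 0 for v in self.label_set):
            raise ValidationError("label_set must contain positive integers only")
        present = set(np.unique(self.voxels).tolist()) - {0}
        unknown = sorted(present - self.label_set)
        if unknown:
            raise LabelError(
                f"voxel values {unknown} are not in the permitted label set "
                f"{sorted(self.label_set)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def present_labels(self) -> set[int]:
        """Positive labels actually occurring in the volume."""
        return set(np.unique(self.voxels).tolist()) - {0}


@dataclass
class BinaryMask:
    """Boolean volume for one label or composite region."""

    voxels: np.ndarray
    label: int | str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValidationError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(np.count_nonzero(self.voxels))


@dataclass
class CandidateEnsemble:
    """A validated collection of co-registered candidate segmentations.

    Construct via :func:`validate_ensemble`, which enforces grid and affine
    consistency.
    """

    candidates: list[MultiClassSegmentation]
    names: list[str]
    shape: tuple[int, int, int]
    affine: np.ndarray

    def __len__(self) -> int:
        return len(self.candidates)


def binarize(
    seg: MultiClassSegmentation, target: int | RegionDefinition | str
) -> BinaryMask:
    """Binary view of one label or composite region of a segmentation.

    ``target`` may be a label integer, a :class:`RegionDefinition`, or a
    region name such as ``"whole_tumor"``.
    """
    if isinstance(target, str):
        try:
            target = REGIONS[target.lower()]
        except KeyError:
            raise LabelError(f"unknown region name {target!r}") from None
    if isinstance(target, RegionDefinition):
        members = target.member_labels
        mask = np.isin(seg.voxels, sorted(members))
        return BinaryMask(mask, target.name)
    label = int(target)
    if label not in seg.label_set:
        raise LabelError(
            f"label {label} not in label set {sorted(seg.label_set)}"
        )
    return BinaryMask(seg.voxels == label, label)


def assemble(
    fused_masks: Mapping[int, BinaryMask],
    precedence: Sequence[int],
    affine: np.ndarray,
    label_set: frozenset[int] | None = None,
) -> MultiClassSegmentation:
    """Recombine per-label binary masks into one multi-class segmentation.

    Masks are painted in ``precedence`` order, later labels overwriting
    earlier ones where masks overlap; voxels true in no mask stay 0.
    ``precedence`` must be a permutation of the mask keys.
    """
    if sorted(precedence) != sorted(fused_masks.keys()):
        raise ValidationError(
            f"precedence {list(precedence)} is not a permutation of the mask "
            f"labels {sorted(fused_masks.keys())}"
        )
    shapes = {m.shape for m in fused_masks.values()}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"masks have inconsistent shapes: {shapes}")
    shape = shapes.pop()
    out = np.zeros(shape, dtype=np.uint8)
    for label in precedence:
        out[fused_masks[label].voxels] = label
    if label_set is None:
        label_set = frozenset(int(l) for l in precedence)
    return MultiClassSegmentation(out, affine, label_set)


def validate_ensemble(
    segs: Sequence[MultiClassSegmentation],
    names: Sequence[str] | None = None,
    strict: bool = False,
    affine_atol: float = AFFINE_ATOL,
) -> CandidateEnsemble:
    """Check mutual consistency of candidates and bundle them.

    All candidates must share an identical voxel grid shape.  Affines must
    agree with the first candidate's within ``affine_atol`` elementwise;
    larger deviations raise in ``strict`` mode and are tolerated (the first
    candidate's affine wins) otherwise.  Candidates must already be
    co-registered — no resampling is ever attempted.
    """
    segs = list(segs)
    if len(segs) < 1:
        raise ValidationError("an ensemble requires at least one candidate")
    if names is None:
        names = [f"c{i + 1:02d}" for i in range(len(segs))]
    names = [str(n) for n in names]
    if len(names) != len(segs):
        raise ValidationError(
            f"{len(segs)} candidates but {len(names)} names"
        )
    ref_shape = segs[0].shape
    ref_affine = segs[0].affine
    for name, seg in zip(names, segs):
        if seg.shape != ref_shape:
            raise ShapeMismatchError(
                f"candidate {name!r} has shape {seg.shape}, expected {ref_shape}"
            )
        dev = float(np.max(np.abs(seg.affine - ref_affine)))
        if dev > affine_atol:
            msg = (
                f"candidate {name!r} affine deviates from the first candidate's "
                f"by {dev:.3g} (> {affine_atol:g})"
            )
            if strict:
                raise ValidationError(msg)
            import logging

            logging.getLogger(__name__).warning("%s; using the first affine", msg)
    return CandidateEnsemble(segs, names, ref_shape, ref_affine.copy())
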