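"""NIfTI reading/writing of label volumes, with BraTS-convention checks.

Input files may store labels as any numeric dtype (many segmentation tools
emit float NIfTI); values are rounded to the nearest integer before
validation, with a tolerance of 1e-3 — a value further from an integer is a
corrupt file, not a label map.  4-D files with a trailing singleton
dimension are squeezed to 3-D.  Label 3 (unused in the BraTS convention) is
rejected rather than silently remapped, so upstream labeling errors stay
visible; an explicit ``remap`` argument exists for datasets that genuinely
use a different coding.

Output is always written as unsigned 8-bit integers (labels ≤ 4), which
guarantees bit-stable round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .exceptions import IOValidationError, LabelError, ShapeMismatchError, ValidationError
from .label_model import BRATS_LABELS, MultiClassSegmentation

#: Maximum distance from an integer tolerated in float-stored label files.
FLOAT_LABEL_ATOL = 1e-3


@dataclass(frozen=True)
class VolumeHeaderInfo:
    """Spatial metadata of a loaded volume, used to stamp outputs."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    source_path: str


def read_header(path) -> VolumeHeaderInfo:
    """Header info (shape, affine) of a NIfTI file without full validation."""
    img = _load(path)
    shape = tuple(int(s) for s in img.shape[:3])
    return VolumeHeaderInfo(shape, np.asarray(img.affine, dtype=float), str(path))


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise IOValidationError(f"no such file: {path}")
    try:
        return nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise IOValidationError(f"cannot read {path} as NIfTI: {exc}") from exc


def read_segmentation(
    path,
    permitted_labels=BRATS_LABELS,
    remap: Mapping[int, int] | None = None,
) -> MultiClassSegmentation:
    """Load a 3-D integer label volume from a NIfTI file.

    Parameters
    ----------
    path
        A ``.nii`` or ``.nii.gz`` file.
    permitted_labels
        Positive labels allowed after rounding (and remapping); anything
        else raises :class:`LabelError` naming the offending values.
    remap
        Optional ``{found_label: replacement}`` applied after rounding,
        e.g. ``{3: 1}`` for datasets using the pre-2017 necrosis coding.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    # squeeze trailing singleton dimensions (common 4-D export artifact)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    rounded = np.rint(data)
    if np.max(np.abs(np.asarray(data, dtype=float) - rounded)) > FLOAT_LABEL_ATOL:
        raise ValidationError(
            f"{path}: voxel values are not integer labels "
            f"(deviation from nearest integer exceeds {FLOAT_LABEL_ATOL})"
        )
    voxels = rounded.astype(np.int64)
    if np.any(voxels < 0):
        raise LabelError(f"{path}: negative label values found")
    if remap:
        out = voxels.copy()
        for src, dst in remap.items():
            out[voxels == int(src)] = int(dst)
        voxels = out
    permitted = frozenset(int(l) for l in permitted_labels)
    present = set(np.unique(voxels).tolist()) - {0}
    unknown = sorted(present - permitted)
    if unknown:
        raise LabelError(
            f"{path}: label values {unknown} are outside the permitted set "
            f"{sorted(permitted)}"
        )
    return MultiClassSegmentation(
        voxels.astype(np.uint8), np.asarray(img.affine, dtype=float), permitted
    )


def write_segmentation(
    seg: MultiClassSegmentation,
    path,
    reference_header: VolumeHeaderInfo | None = None,
) -> None:
    """Write a segmentation as a uint8 NIfTI-1 file.

    If ``reference_header`` is given (by convention, the first candidate's
    header), its affine is stamped on the output and its shape must match.
    """
    affine = seg.affine
    if reference_header is not None:
        if tuple(reference_header.shape) != seg.shape:
            raise ShapeMismatchError(
                f"segmentation shape {seg.shape} does not match reference "
                f"header shape {tuple(reference_header.shape)}"
            )
        affine = np.asarray(reference_header.affine, dtype=float)
    img = nib.Nifti1Image(seg.voxels.astype(np.uint8), affine)
    img.header.set_data_dtype(np.uint8)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise IOValidationError(f"cannot write {path}: {exc}") from exc
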