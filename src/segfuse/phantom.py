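"""Synthetic ground-truth tumors and simulated rater ensembles.

The phantom emulates the nested anatomy of a glioma label map: an outer
edema ellipsoid (label 2) enclosing a tumor-core ellipsoid whose rim is
enhancing tumor (label 4) and whose interior is necrosis (label 1), so the
composite regions nest exactly as in real data (ET ⊂ TC ⊂ WT).

Simulated raters degrade the ground truth with three controllable error
modes: per-label morphological boundary noise (random dilation/erosion with
a spherical structuring element), random deletion of a fraction of tumor
voxels (false negatives), and spurious spherical blobs placed fully outside
the true tumor (false positives — the kind of isolated outlier consensus
fusion is expected to remove).

Everything is deterministic given the seeds.  Each object carries a single
integer seed that is expanded internally with a counter-based scheme
(``default_rng([seed, stage])``), so each noise stage draws from its own
stream and candidates are reproducible independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .exceptions import ValidationError
from .label_model import (
    CandidateEnsemble,
    MultiClassSegmentation,
    WHOLE_TUMOR,
    binarize,
    validate_ensemble,
)

_TUMOR_LABELS = (2, 1, 4)  # precedence order used when recombining noisy labels


@dataclass
class PhantomParams:
    """Geometry and seed of a synthetic ground-truth tumor.

    Three concentric ellipsoids (semi-axis radii in voxels) define the
    anatomy: ``edema_radii`` ⊃ ``core_radii`` ⊃ ``necrosis_radii``.  The
    seed jitters the common center (±2 voxels) and the radii (±10%) so that
    different seeds give geometrically distinct but always-valid phantoms.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    center: tuple[float, float, float] | None = None
    edema_radii: tuple[float, float, float] = (18.0, 14.0, 10.0)
    core_radii: tuple[float, float, float] = (10.0, 8.0, 6.0)
    necrosis_radii: tuple[float, float, float] = (5.0, 4.0, 3.0)
    seed: int = 0


@dataclass
class RaterProfile:
    """Error model of one simulated rater.

    Parameters
    ----------
    boundary_noise
        Maximum radius (voxels) of the random per-label dilation/erosion;
        the actual radius is drawn uniformly from 0..boundary_noise per
        label.
    fp_blob_count, fp_blob_radius
        Number and radius of spurious spherical blobs of a random tumor
        label placed fully outside the true whole tumor.
    fn_rate
        Fraction of the rater's tumor voxels deleted at random, in [0, 1).
    """

    boundary_noise: int = 0
    fp_blob_count: int = 0
    fp_blob_radius: int = 2
    fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_noise < 0:
            raise ValidationError("boundary_noise must be >= 0")
        if self.fp_blob_count < 0:
            raise ValidationError("fp_blob_count must be >= 0")
        if self.fp_blob_radius < 1:
            raise ValidationError("fp_blob_radius must be >= 1")
        if not 0.0 <= self.fn_rate < 1.0:
            raise ValidationError("fn_rate must be in [0, 1)")


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_phantom(params: PhantomParams) -> MultiClassSegmentation:
    """Deterministic nested-ellipsoid ground truth with labels {0, 1, 2, 4}."""
    shape = tuple(int(s) for s in params.shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ValidationError(f"invalid phantom shape {shape}")
    rng = _rng(params.seed, 0)
    center = params.center
    if center is None:
        center = tuple(s / 2.0 for s in shape)
    center = tuple(float(c) + dx for c, dx in zip(center, rng.uniform(-2, 2, 3)))
    scale = rng.uniform(0.9, 1.1)
    radii = {
        "edema": tuple(r * scale for r in params.edema_radii),
        "core": tuple(r * scale for r in params.core_radii),
        "necrosis": tuple(r * scale for r in params.necrosis_radii),
    }
    for a, b in (("necrosis", "core"), ("core", "edema")):
        if any(ra > rb for ra, rb in zip(radii[a], radii[b])):
            raise ValidationError(
                f"{a} radii {radii[a]} must nest inside {b} radii {radii[b]}"
            )
    for c, r, s in zip(center, radii["edema"], shape):
        if c - r < 0.5 or c + r > s - 0.5:
            raise ValidationError(
                f"edema ellipsoid (center {center}, radii {radii['edema']}) "
                f"exceeds the {shape} grid"
            )
    edema = _ellipsoid_mask(shape, center, radii["edema"])
    core = _ellipsoid_mask(shape, center, radii["core"])
    necrosis = _ellipsoid_mask(shape, center, radii["necrosis"])
    voxels = np.zeros(shape, dtype=np.uint8)
    voxels[edema] = 2
    voxels[core] = 4  # enhancing rim: core minus necrotic interior
    voxels[necrosis] = 1
    return MultiClassSegmentation(voxels, np.eye(4), frozenset({1, 2, 4}))


def _random_morphology(mask: np.ndarray, max_radius: int, rng) -> np.ndarray:
    radius = int(rng.integers(0, max_radius + 1))
    if radius == 0:
        return mask
    selem = ball(radius)
    if rng.integers(0, 2) == 0:
        return ndimage.binary_dilation(mask, structure=selem)
    return ndimage.binary_erosion(mask, structure=selem)


def add_blob(
    seg: MultiClassSegmentation,
    center: tuple[int, int, int],
    radius: int,
    label: int,
) -> MultiClassSegmentation:
    """Return a copy of ``seg`` with a spherical blob of ``label`` painted in."""
    if label not in seg.label_set:
        raise ValidationError(f"label {label} not in label set")
    blob = _ellipsoid_mask(seg.shape, center, (radius,) * 3)
    voxels = seg.voxels.copy()
    voxels[blob] = label
    return MultiClassSegmentation(voxels, seg.affine.copy(), seg.label_set)


def simulate_candidate(
    gt: MultiClassSegmentation, profile: RaterProfile
) -> MultiClassSegmentation:
    """One imperfect rater's segmentation of the phantom ground truth."""
    shape = gt.shape
    voxels = np.zeros(shape, dtype=np.uint8)
    for stage, label in enumerate(_TUMOR_LABELS):
        mask = gt.voxels == label
        if profile.boundary_noise > 0 and mask.any():
            mask = _random_morphology(
                mask, profile.boundary_noise, _rng(profile.seed, stage)
            )
        voxels[mask] = label

    if profile.fn_rate > 0:
        rng = _rng(profile.seed, 10)
        positive = np.flatnonzero(voxels)
        n_delete = int(round(profile.fn_rate * positive.size))
        if n_delete > 0:
            drop = rng.choice(positive, size=n_delete, replace=False)
            voxels.flat[drop] = 0

    if profile.fp_blob_count > 0:
        # blobs must lie fully outside (and not touch) the true whole tumor
        exclusion = ndimage.binary_dilation(
            binarize(gt, WHOLE_TUMOR).voxels, structure=ball(1)
        )
        r = profile.fp_blob_radius
        if any(s <= 2 * r for s in shape):
            raise ValidationError(
                f"fp_blob_radius {r} too large for grid {shape}"
            )
        for blob_idx in range(profile.fp_blob_count):
            rng = _rng(profile.seed, 20 + blob_idx)
            label = int(rng.choice(_TUMOR_LABELS))
            for _ in range(200):
                center = tuple(
                    int(rng.integers(r, s - r)) for s in shape
                )
                blob = _ellipsoid_mask(shape, center, (r,) * 3)
                if not np.any(blob & exclusion):
                    voxels[blob] = label
                    break
            else:
                raise ValidationError(
                    "could not place a false-positive blob outside the tumor "
                    "after 200 attempts (tumor fills the grid?)"
                )

    return MultiClassSegmentation(voxels, gt.affine.copy(), gt.label_set)


def generate_ensemble(
    gt: MultiClassSegmentation, profiles: list[RaterProfile]
) -> CandidateEnsemble:
    """Simulate one candidate per profile and validate them as an ensemble."""
    if len(profiles) < 1:
        raise ValidationError("at least one rater profile is required")
    candidates = [simulate_candidate(gt, p) for p in profiles]
    names = [f"r{i + 1:02d}" for i in range(len(profiles))]
    return validate_ensemble(candidates, names)


def _child_seeds(seed: int, n: int) -> list[int]:
    # independent 31-bit child seeds from one master seed
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


#: Quality tiers of competent raters.  A real candidate panel consists of
#: different algorithms of varying accuracy, so the mild raters span a
#: spread of noise levels (WT dice roughly 0.92-0.995 on the default
#: phantom) rather than sharing one profile.
_MILD_TIERS = (
    dict(boundary_noise=0, fp_blob_count=1, fp_blob_radius=2, fn_rate=0.01),
    dict(boundary_noise=1, fp_blob_count=1, fp_blob_radius=2, fn_rate=0.03),
    dict(boundary_noise=1, fp_blob_count=2, fp_blob_radius=2, fn_rate=0.05),
    dict(boundary_noise=2, fp_blob_count=2, fp_blob_radius=3, fn_rate=0.08),
)


def mild_profile(seed: int, tier: int = 0) -> RaterProfile:
    """A competent rater: slight boundary noise, rare misses, a stray blob.

    ``tier`` (0-3) selects increasing noise levels.
    """
    return RaterProfile(**_MILD_TIERS[tier % len(_MILD_TIERS)], seed=seed)


def corrupted_profile(seed: int) -> RaterProfile:
    """A failed segmentation: most tumor missed, several large spurious blobs."""
    return RaterProfile(
        boundary_noise=2, fp_blob_count=6, fp_blob_radius=4, fn_rate=0.85, seed=seed
    )


def study_profiles(
    n_mild: int, n_corrupted: int, seed: int
) -> list[RaterProfile]:
    """The standard simulated-rater panel: mild raters first, corrupted last.

    Mild raters cycle through the quality tiers so the panel varies in
    accuracy, as a panel of distinct segmentation algorithms does.
    """
    seeds = _child_seeds(seed, n_mild + n_corrupted)
    return [mild_profile(s, tier=i) for i, s in enumerate(seeds[:n_mild])] + [
        corrupted_profile(s) for s in seeds[n_mild:]
    ]
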