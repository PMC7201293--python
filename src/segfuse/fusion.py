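"""Consensus fusion of candidate segmentations.

Two class-wise fusion methods are provided:

* **Majority voting (MAV)** — per voxel, a class is assigned when at least
  half of the candidates (by weight; unweighted for plain MAV) agree that
  the voxel carries that class.  Ties at exactly half are included.

* **SIMPLE** — the selective and iterative method for performance level
  estimation.  Per class: start from the unweighted majority vote of all
  candidates; then repeatedly (1) score every retained candidate against the
  current consensus with the Dice coefficient, (2) drop candidates whose
  score falls below the threshold τ = max(0, mean(φ) − α·std(φ)) computed
  once from the full panel's first-iteration scores, (3) re-vote with the
  Dice scores (raised to an exponent p) as weights.
  The loop stops when the consensus volume and the retained set both stop
  changing, or after ``max_iter`` iterations.

Both methods fuse each label (or nested region) independently and recombine
the per-class results with a precedence overwrite, yielding a single
multi-class segmentation plus a :class:`FusionReport` audit trail.

Both methods are deterministic and RNG-free: identical inputs give
bit-identical outputs regardless of candidate order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ShapeMismatchError, ValidationError
from .label_model import (
    BinaryMask,
    CandidateEnsemble,
    DEFAULT_PRECEDENCE,
    ENHANCING_TUMOR,
    MultiClassSegmentation,
    TUMOR_CORE,
    WHOLE_TUMOR,
    assemble,
    binarize,
)
from .metrics import _dice_arrays

#: In region mode the nested region masks (WT ⊃ TC ⊃ ET) are decoded back to
#: raw labels by painting WT as edema, then TC as necrosis, then ET as
#: enhancing tumor — the precedence overwrite recovers the nesting.
_REGION_DECODE = ((2, WHOLE_TUMOR), (1, TUMOR_CORE), (4, ENHANCING_TUMOR))


@dataclass
class FusionParams:
    """Tunables of both fusion methods.

    Parameters
    ----------
    method
        ``"mav"`` or ``"simple"``.
    labels
        Labels to fuse, in precedence order (later overwrite earlier on
        recombination).  Default ``(2, 1, 4)``.
    mode
        ``"raw_labels"`` fuses each label independently; ``"regions"`` fuses
        the nested composites WT/TC/ET and decodes them back by nesting.
    alpha
        Dropout stringency: candidates scoring below mean(φ) − alpha·std(φ)
        are removed.  0 disables adaptive dropout.  Default 1.0.
    weight_exponent
        Exponent p applied to the Dice score when used as a voting weight.
        p = 1 uses raw Dice; larger p sharpens the weighting.  Default 1.0.
    max_iter
        Iteration cap for the SIMPLE loop.  Default 25.
    """

    method: str = "simple"
    labels: tuple[int, ...] = DEFAULT_PRECEDENCE
    mode: str = "raw_labels"
    alpha: float = 1.0
    weight_exponent: float = 1.0
    max_iter: int = 25
    tie_rule: str = "at-least-half"

    def __post_init__(self) -> None:
        if self.method not in ("mav", "simple"):
            raise ValidationError(f"unknown fusion method {self.method!r}")
        if self.mode not in ("raw_labels", "regions"):
            raise ValidationError(f"unknown fusion mode {self.mode!r}")
        self.labels = tuple(int(l) for l in self.labels)
        if len(set(self.labels)) != len(self.labels) or not self.labels:
            raise ValidationError("labels must be a non-empty list without duplicates")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.weight_exponent <= 0:
            raise ValidationError("weight_exponent must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tie_rule != "at-least-half":
            raise ValidationError("only the 'at-least-half' tie rule is supported")


@dataclass
class IterationRecord:
    """One SIMPLE iteration: who was scored, how, who survived."""

    phi: dict[str, float]
    tau: float
    retained: list[str]
    consensus_voxels: int


@dataclass
class ClassFusionTrace:
    """Audit trail for the fusion of one class."""

    target: str
    candidate_names: list[str]
    iterations: list[IterationRecord] = field(default_factory=list)
    converged: bool = False
    iterations_run: int = 0

    @property
    def retained_final(self) -> list[str]:
        if not self.iterations:
            return list(self.candidate_names)
        return list(self.iterations[-1].retained)

    @property
    def dropped(self) -> list[str]:
        final = set(self.retained_final)
        return [n for n in self.candidate_names if n not in final]


@dataclass
class FusionReport:
    """Per-class traces plus an echo of the parameters used."""

    method: str
    params: FusionParams
    traces: dict[str, ClassFusionTrace] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": asdict(self.params),
            "traces": {
                target: {
                    "candidates": tr.candidate_names,
                    "converged": tr.converged,
                    "iterations_run": tr.iterations_run,
                    "retained_final": tr.retained_final,
                    "dropped": tr.dropped,
                    "iterations": [asdict(it) for it in tr.iterations],
                }
                for target, tr in self.traces.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _stack(masks: Sequence[BinaryMask]) -> np.ndarray:
    if len(masks) == 0:
        raise ValidationError("at least one mask is required")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"mask shapes differ: {shapes}")
    return np.stack([m.voxels for m in masks], axis=0)


def weighted_majority(
    masks: Sequence[BinaryMask], weights: Sequence[float]
) -> BinaryMask:
    """Weighted per-voxel vote: true where ≥ half the total weight agrees.

    A voxel is included when the summed weight of masks voting "true" there
    is at least 0.5 times the total weight — a tie at exactly half counts as
    agreement ("at least half").
    """
    stack = _stack(masks)
    w = np.asarray(list(weights), dtype=float)
    if w.ndim != 1 or len(w) != len(masks):
        raise ValidationError(
            f"{len(masks)} masks but {w.size} weights"
        )
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    total = float(w.sum())
    if total <= 0:
        raise ValidationError("weights must not all be zero")
    votes = np.tensordot(w, stack, axes=(0, 0))
    fused = votes >= 0.5 * total - 1e-12 * total  # tolerate float summation noise
    return BinaryMask(fused, masks[0].label)


def majority(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Unweighted majority vote (all weights equal)."""
    return weighted_majority(masks, np.ones(len(masks)))


def simple_fuse_class(
    masks: Sequence[BinaryMask],
    names: Sequence[str],
    params: FusionParams,
) -> tuple[BinaryMask, ClassFusionTrace]:
    """Run the SIMPLE loop on the binary masks of one class.

    Returns the converged (or capped) consensus mask and a trace recording,
    per iteration, each scored candidate's Dice against the consensus (φ),
    the dropout threshold τ, the surviving candidate names, and the
    consensus voxel count.
    """
    masks = list(masks)
    names = [str(n) for n in names]
    if len(masks) != len(names):
        raise ValidationError(f"{len(masks)} masks but {len(names)} names")
    stack = _stack(masks)
    target = masks[0].label
    trace = ClassFusionTrace(target=str(target), candidate_names=list(names))

    consensus = majority(masks).voxels
    retained = list(range(len(masks)))
    tau: float | None = None

    for iteration in range(1, params.max_iter + 1):
        phi = np.array([_dice_arrays(stack[i], consensus) for i in retained])
        if tau is None:
            # stringency fixed from the full panel's score distribution
            # (population std; clamped at 0).  Recomputing it over the
            # shrinking survivor set would make the cut an order statistic
            # of survivor noise and cascade until ~2 candidates remain.
            tau = max(0.0, float(phi.mean() - params.alpha * phi.std()))
        best = retained[int(np.argmax(phi))]
        new_retained = [
            i for i, p in zip(retained, phi) if p >= tau or i == best
        ]
        weights = np.array(
            [phi[retained.index(i)] ** params.weight_exponent for i in new_retained]
        )
        if weights.sum() <= 0:
            # all retained candidates disagree totally with the consensus;
            # fall back to an unweighted vote so the consensus stays defined
            weights = np.ones(len(new_retained))
        new_consensus = weighted_majority(
            [masks[i] for i in new_retained], weights
        ).voxels

        trace.iterations.append(
            IterationRecord(
                phi={names[i]: float(p) for i, p in zip(retained, phi)},
                tau=tau,
                retained=[names[i] for i in new_retained],
                consensus_voxels=int(np.count_nonzero(new_consensus)),
            )
        )
        trace.iterations_run = iteration
        if new_retained == retained and np.array_equal(new_consensus, consensus):
            trace.converged = True
            consensus = new_consensus
            break
        retained, consensus = new_retained, new_consensus

    return BinaryMask(consensus, target), trace


def _class_targets(params: FusionParams):
    """(output label, binarization target) pairs for the configured mode."""
    if params.mode == "regions":
        return list(_REGION_DECODE)
    return [(label, label) for label in params.labels]


def _fuse(
    ensemble: CandidateEnsemble, params: FusionParams
) -> tuple[MultiClassSegmentation, FusionReport]:
    report = FusionReport(method=params.method, params=params)
    fused_masks: dict[int, BinaryMask] = {}
    precedence: list[int] = []
    for out_label, target in _class_targets(params):
        masks = [binarize(c, target) for c in ensemble.candidates]
        if params.method == "mav":
            fused = majority(masks)
            trace = ClassFusionTrace(
                target=str(masks[0].label),
                candidate_names=list(ensemble.names),
                iterations=[
                    IterationRecord(
                        phi={},
                        tau=0.0,
                        retained=list(ensemble.names),
                        consensus_voxels=fused.count(),
                    )
                ],
                converged=True,
                iterations_run=1,
            )
        else:
            fused, trace = simple_fuse_class(masks, ensemble.names, params)
        fused_masks[out_label] = fused
        precedence.append(out_label)
        report.traces[trace.target] = trace
    label_set = frozenset(
        set(precedence) | set().union(*(c.label_set for c in ensemble.candidates))
    )
    seg = assemble(fused_masks, precedence, ensemble.affine, label_set=label_set)
    return seg, report


def mav(
    ensemble: CandidateEnsemble, params: FusionParams | None = None
) -> tuple[MultiClassSegmentation, FusionReport]:
    """Class-wise unweighted majority-vote fusion."""
    params = FusionParams(**{**(asdict(params) if params else {}), "method": "mav"})
    return _fuse(ensemble, params)


def simple(
    ensemble: CandidateEnsemble, params: FusionParams | None = None
) -> tuple[MultiClassSegmentation, FusionReport]:
    """Class-wise iterative SIMPLE fusion with candidate dropout."""
    params = FusionParams(**{**(asdict(params) if params else {}), "method": "simple"})
    return _fuse(ensemble, params)


def fuse(
    ensemble: CandidateEnsemble, params: FusionParams
) -> tuple[MultiClassSegmentation, FusionReport]:
    """Dispatch on ``params.method``."""
    return _fuse(ensemble, params)
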