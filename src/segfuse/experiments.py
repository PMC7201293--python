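"""Reusable synthetic-fusion experiments.

Two study designs, both fully determined by a single integer seed, shared
by the examples, the test suite and the reproduction script:

* :func:`fp_removal_experiment` — ten near-perfect candidates of which four
  carry an *identical* spurious blob outside the tumor; measures whether
  each fusion method removes the blob while preserving whole-tumor overlap.

* :func:`fusion_vs_individuals_experiment` — a panel of seven mild-noise
  raters of varying quality plus three heavily corrupted ones; measures the
  SIMPLE fusion's whole-tumor Dice against the individual candidates and
  whether the corrupted raters are dropped from the retained set.

Whole-tumor numbers are computed with the nested-region fusion mode, the
configuration a whole-tumor evaluation exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fusion import FusionParams, FusionReport, fuse
from .label_model import WHOLE_TUMOR, binarize, validate_ensemble
from .metrics import dice
from .phantom import (
    PhantomParams,
    RaterProfile,
    _child_seeds,
    _ellipsoid_mask,
    add_blob,
    generate_ensemble,
    generate_phantom,
    simulate_candidate,
    study_profiles,
)

#: Shared-blob geometry for the false-positive experiment: a sphere in the
#: image corner, comfortably outside the default phantom's tumor.
_BLOB_CENTER = (10, 10, 8)
_BLOB_RADIUS = 3


@dataclass
class FpRemovalResult:
    """Outcome of the shared-false-positive experiment for one method."""

    method: str
    blob_voxels_in_fusion: int
    wt_dice: float


def fp_removal_experiment(
    seed: int,
    n_candidates: int = 10,
    n_carriers: int = 4,
) -> dict[str, FpRemovalResult]:
    """Fuse candidates of which ``n_carriers`` share one spurious blob.

    The base candidates carry only minimal independent noise (1% random
    misses) so the experiment isolates the consensus mechanism's handling
    of a correlated false positive.  Returns one result per fusion method.
    """
    gt = generate_phantom(PhantomParams(seed=seed))
    seeds = _child_seeds(seed, n_candidates)
    profiles = [
        RaterProfile(boundary_noise=0, fp_blob_count=0, fn_rate=0.01, seed=s)
        for s in seeds
    ]
    candidates = []
    for i, p in enumerate(profiles):
        cand = simulate_candidate(gt, p)
        if i < n_carriers:
            cand = add_blob(cand, _BLOB_CENTER, _BLOB_RADIUS, 4)
        candidates.append(cand)
    blob = _ellipsoid_mask(gt.shape, _BLOB_CENTER, (_BLOB_RADIUS,) * 3)
    gt_wt = binarize(gt, WHOLE_TUMOR)
    if np.any(blob & gt_wt.voxels):
        raise RuntimeError("blob geometry overlaps the phantom tumor")
    ensemble = validate_ensemble(candidates)
    results: dict[str, FpRemovalResult] = {}
    for method in ("mav", "simple"):
        fused, _ = fuse(ensemble, FusionParams(method=method, mode="regions"))
        fused_wt = binarize(fused, WHOLE_TUMOR)
        results[method] = FpRemovalResult(
            method=method,
            blob_voxels_in_fusion=int(np.count_nonzero(fused_wt.voxels & blob)),
            wt_dice=dice(fused_wt, gt_wt).value,
        )
    return results


@dataclass
class PanelRun:
    """One seed of the mild-vs-corrupted panel experiment."""

    seed: int
    individual_wt_dice: list[float]  # mild raters first, corrupted last
    simple_wt_dice: float
    mav_wt_dice: float
    corrupted_names: list[str]
    corrupted_dropped: bool  # all corrupted absent from final WT retained set
    converged: bool  # every class trace converged
    max_iterations: int
    report: FusionReport = field(repr=False, default=None)


def run_panel(seed: int, n_mild: int = 7, n_corrupted: int = 3) -> PanelRun:
    """Generate one rater panel, fuse it, and score everything against gt."""
    gt = generate_phantom(PhantomParams(seed=seed))
    ensemble = generate_ensemble(gt, study_profiles(n_mild, n_corrupted, seed))
    gt_wt = binarize(gt, WHOLE_TUMOR)
    individual = [
        dice(binarize(c, WHOLE_TUMOR), gt_wt).value for c in ensemble.candidates
    ]
    params = FusionParams(method="simple", mode="regions")
    fused_s, report = fuse(ensemble, params)
    fused_m, _ = fuse(ensemble, FusionParams(method="mav", mode="regions"))
    corrupted = ensemble.names[n_mild:]
    wt_trace = report.traces[WHOLE_TUMOR.name]
    return PanelRun(
        seed=seed,
        individual_wt_dice=individual,
        simple_wt_dice=dice(binarize(fused_s, WHOLE_TUMOR), gt_wt).value,
        mav_wt_dice=dice(binarize(fused_m, WHOLE_TUMOR), gt_wt).value,
        corrupted_names=list(corrupted),
        corrupted_dropped=all(n not in wt_trace.retained_final for n in corrupted),
        converged=all(t.converged for t in report.traces.values()),
        max_iterations=max(t.iterations_run for t in report.traces.values()),
        report=report,
    )


@dataclass
class PanelSummary:
    """Aggregate over seeds of the panel experiment."""

    runs: list[PanelRun]

    @property
    def n(self) -> int:
        return len(self.runs)

    @property
    def frac_ge_best_candidate(self) -> float:
        return float(
            np.mean(
                [r.simple_wt_dice >= max(r.individual_wt_dice) for r in self.runs]
            )
        )

    @property
    def frac_ge_median_candidate(self) -> float:
        return float(
            np.mean(
                [
                    r.simple_wt_dice >= np.median(r.individual_wt_dice)
                    for r in self.runs
                ]
            )
        )

    @property
    def frac_corrupted_dropped(self) -> float:
        return float(np.mean([r.corrupted_dropped for r in self.runs]))

    @property
    def median_simple_wt_dice(self) -> float:
        return float(np.median([r.simple_wt_dice for r in self.runs]))

    @property
    def median_best_individual_wt_dice(self) -> float:
        return float(np.median([max(r.individual_wt_dice) for r in self.runs]))


def fusion_vs_individuals_experiment(
    seed: int, n_seeds: int = 20, n_mild: int = 7, n_corrupted: int = 3
) -> PanelSummary:
    """Run the panel experiment over ``n_seeds`` derived seeds."""
    seeds = _child_seeds(seed, n_seeds)
    return PanelSummary([run_panel(s, n_mild, n_corrupted) for s in seeds])
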