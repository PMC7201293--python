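"""Independent straight-line reference implementations used as oracles.

These deliberately avoid the package's vectorized code paths: votes are
tallied per voxel in plain Python loops and the SIMPLE loop is written as a
direct transliteration of its textual description, so agreement with the
package is meaningful.
"""

from __future__ import annotations

import numpy as np


def brute_force_weighted_majority(
    masks: list[np.ndarray], weights: list[float]
) -> np.ndarray:
    """Per-voxel tally: true where the agreeing weight is >= half the total."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    shape = masks[0].shape
    total = sum(weights)
    out = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(shape):
        agreeing = sum(w for m, w in zip(masks, weights) if m[idx])
        out[idx] = agreeing >= 0.5 * total
    return out


def reference_dice(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def reference_simple_loop(
    masks: list[np.ndarray],
    alpha: float = 1.0,
    exponent: float = 1.0,
    max_iter: int = 25,
) -> tuple[np.ndarray, list[list[int]], bool]:
    """Straight-line SIMPLE: returns (consensus, retained-per-iteration, converged).

    Semantics: consensus starts as the unweighted majority of all masks.
    Each iteration scores the retained masks against the consensus with
    Dice, drops those scoring below the threshold mean - alpha*std (threshold
    fixed from the first iteration's full-panel scores, clamped at 0, the
    top scorer never dropped), and re-votes the survivors with dice**exponent
    weights (equal weights if all scores are 0).  Converged when both the
    consensus and the retained set stop changing.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    consensus = brute_force_weighted_majority(masks, [1.0] * len(masks))
    retained = list(range(len(masks)))
    history: list[list[int]] = []
    converged = False
    threshold = None
    for _ in range(max_iter):
        scores = [reference_dice(masks[i], consensus) for i in retained]
        if threshold is None:
            mean = sum(scores) / len(scores)
            var = sum((s - mean) ** 2 for s in scores) / len(scores)
            threshold = max(0.0, mean - alpha * var**0.5)
        best = retained[scores.index(max(scores))]
        survivors = [
            i
            for i, s in zip(retained, scores)
            if s >= threshold or i == best
        ]
        weights = [
            scores[retained.index(i)] ** exponent for i in survivors
        ]
        if sum(weights) <= 0:
            weights = [1.0] * len(survivors)
        new_consensus = brute_force_weighted_majority(
            [masks[i] for i in survivors], weights
        )
        history.append(list(survivors))
        if survivors == retained and bool(np.array_equal(new_consensus, consensus)):
            converged = True
            consensus = new_consensus
            break
        retained, consensus = survivors, new_consensus
    return consensus, history, converged
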