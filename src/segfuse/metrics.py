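"""Overlap metrics: the Dice coefficient and multi-target evaluation.

The Dice similarity coefficient between two binary masks A and B is

    DSC = 2|A ∩ B| / (|A| + |B|),

a value in [0, 1].  It serves double duty here: as the evaluation metric
against a reference segmentation, and inside the SIMPLE loop as the
performance estimate of each candidate against the current consensus.

Degenerate-case conventions: two empty masks score 1.0 (perfect agreement
that the class is absent), an empty vs. a non-empty mask scores 0.0.  The
first convention matters inside SIMPLE — a candidate that correctly reports
an absent class must not be penalized and dropped for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ShapeMismatchError
from .label_model import BinaryMask, MultiClassSegmentation, RegionDefinition, binarize


@dataclass(frozen=True)
class OverlapScore:
    """A scalar overlap value in [0, 1]."""

    value: float
    metric_name: str = "dice"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"overlap score {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    """Dice on boolean arrays; shared fast path for metrics and fusion."""
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(np.count_nonzero(a))
    nb = int(np.count_nonzero(b))
    if na + nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def dice(a: BinaryMask, b: BinaryMask) -> OverlapScore:
    """Dice coefficient of two binary masks (empty/empty := 1.0)."""
    return OverlapScore(_dice_arrays(a.voxels, b.voxels))


@dataclass
class EvaluationReport:
    """Per-target Dice scores of one candidate against one reference."""

    scores: dict[int | str, OverlapScore]
    candidate_name: str = "candidate"
    reference_name: str = "reference"
    extra: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "candidate": self.candidate_name,
                "reference": self.reference_name,
                "target": str(t),
                "dice": s.value,
            }
            for t, s in self.scores.items()
        ]
        return pd.DataFrame(rows, columns=["candidate", "reference", "target", "dice"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def evaluate(
    candidate: MultiClassSegmentation,
    reference: MultiClassSegmentation,
    targets: list[int | str | RegionDefinition],
    candidate_name: str = "candidate",
    reference_name: str = "reference",
) -> EvaluationReport:
    """Dice of ``candidate`` vs ``reference`` for each label/region target."""
    if candidate.shape != reference.shape:
        raise ShapeMismatchError(
            f"candidate shape {candidate.shape} != reference shape {reference.shape}"
        )
    scores: dict[int | str, OverlapScore] = {}
    for target in targets:
        ca = binarize(candidate, target)
        re = binarize(reference, target)
        key = ca.label
        scores[key] = dice(ca, re)
    return EvaluationReport(scores, candidate_name, reference_name)
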