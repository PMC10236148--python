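"""Per-sample de novo confidence-score threshold calibration.

Given scored de novo predictions paired with database-search ground truth
on a validation set, choose the smallest score threshold whose retained
subset reaches a target sequence-level accuracy (default 90%).  Sequence
identity treats leucine and isoleucine as interchangeable because they are
isobaric and indistinguishable by standard tandem MS.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

_PTM_ANNOTATION = re.compile(r"[\(\[][^)\]]*[\)\]]|[a-z+\-0-9.]")


@dataclass(frozen=True)
class ScoredPrediction:
    predicted_sequence: str
    true_sequence: str
    score: float

    def __post_init__(self) -> None:
        if not self.predicted_sequence or not self.true_sequence:
            raise ValueError("sequences must be non-empty")


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    achieved_accuracy: float
    retained_fraction: float
    attainable: bool


def strip_ptm_annotations(seq: str) -> str:
    """Remove inline PTM mass/site annotations, keeping the backbone."""
    return _PTM_ANNOTATION.sub("", seq)


def sequences_equivalent(pred: str, truth: str) -> bool:
    """Whole-sequence equality with I and L interchangeable."""
    pred = strip_ptm_annotations(pred)
    truth = strip_ptm_annotations(truth)
    if len(pred) != len(truth):
        return False
    return pred.replace("I", "L") == truth.replace("I", "L")


def residue_accuracy(pred: str, truth: str) -> float:
    """Fraction of aligned positions matching under I==L (0 on length
    mismatch); alternative accuracy mode."""
    pred = strip_ptm_annotations(pred)
    truth = strip_ptm_annotations(truth)
    if len(pred) != len(truth) or not truth:
        return 0.0
    p, t = pred.replace("I", "L"), truth.replace("I", "L")
    return sum(a == b for a, b in zip(p, t)) / len(t)


def calibrate_threshold(
    preds: list[ScoredPrediction],
    target: float = 0.90,
    level: str = "sequence",
) -> ThresholdResult:
    """Smallest candidate threshold t (over distinct scores) such that
    accuracy over {score >= t} is >= target; ties break toward the larger
    retained set.  When even the best-scoring subset misses the target the
    result is flagged unattainable with an infinite threshold.
    """
    if not preds:
        raise ValueError("need at least one scored prediction")
    if level == "sequence":
        correct = [
            1.0 if sequences_equivalent(p.predicted_sequence, p.true_sequence)
            else 0.0
            for p in preds
        ]
    elif level == "residue":
        correct = [
            residue_accuracy(p.predicted_sequence, p.true_sequence)
            for p in preds
        ]
    else:
        raise ValueError(f"unknown accuracy level {level!r}")
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    n = len(preds)
    # cumulative accuracy of the top-k retained set
    best: ThresholdResult | None = None
    acc_sum = 0.0
    k = 0
    i = 0
    while i < n:
        # extend through ties so every retained set is {score >= t}
        t = preds[order[i]].score
        while i < n and preds[order[i]].score == t:
            acc_sum += correct[order[i]]
            k += 1
            i += 1
        acc = acc_sum / k
        if acc >= target:
            best = ThresholdResult(
                threshold=t, achieved_accuracy=acc,
                retained_fraction=k / n, attainable=True,
            )
    if best is None:
        return ThresholdResult(
            threshold=math.inf, achieved_accuracy=0.0,
            retained_fraction=0.0, attainable=False,
        )
    return best
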