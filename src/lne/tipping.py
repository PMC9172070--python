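"""Stage-wise aggregation of sample scores and tipping-point calling.

Per-sample global scores are averaged within each clinical stage (in a
user-supplied clinical order — stage labels do not sort
lexicographically) and the critical transition is called either at the
score peak or at the largest stage-to-stage increase. Ties break toward
the earlier stage, the earliest possible warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from lne.entropy import SampleScore
from lne.survival import LogRankResult, SurvivalRecord, logrank_test

logger = logging.getLogger(__name__)

__all__ = ["StageCurve", "TransitionSurvival", "stage_curve", "call_transition", "before_after_survival"]


@dataclass
class StageCurve:
    stages: tuple[str, ...]
    mean_scores: tuple[float, ...]
    counts: tuple[int, ...]
    transition_stage: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stage": self.stages, "n": self.counts, "mean_global_dE": self.mean_scores}
        )


@dataclass
class TransitionSurvival:
    transition_stage: str
    before_n: int
    after_n: int
    result: LogRankResult


def stage_curve(scores: Sequence[SampleScore], stage_order: Sequence[str]) -> StageCurve:
    """Mean global score per stage, stages in the given clinical order.

    Stages with no samples are dropped with a warning; fewer than two
    populated stages is an error.
    """
    order = list(stage_order)
    unknown = sorted({s.stage for s in scores} - set(order))
    if unknown:
        raise ValueError(f"sample stages not in stage_order: {unknown}")
    stages, means, counts = [], [], []
    for stage in order:
        vals = [s.global_dE for s in scores if s.stage == stage]
        if not vals:
            logger.warning("stage %r has no samples; dropped from the curve", stage)
            continue
        stages.append(stage)
        means.append(float(np.mean(vals)))
        counts.append(len(vals))
    if len(stages) < 2:
        raise ValueError(f"need >= 2 populated stages, got {len(stages)}")
    return StageCurve(stages=tuple(stages), mean_scores=tuple(means), counts=tuple(counts))


def call_transition(curve: StageCurve, method: str = "peak") -> str:
    """Call the critical transition stage from a stage curve.

    ``peak``: stage with the maximal mean score. ``max_increase``: stage
    maximizing the increase over its predecessor. Ties break to the
    earlier stage.
    """
    if len(curve.stages) < 2:
        raise ValueError("stage curve has fewer than 2 stages")
    means = np.asarray(curve.mean_scores)
    if method == "peak":
        idx = int(np.argmax(means))  # argmax returns the first maximum
    elif method == "max_increase":
        deltas = np.diff(means)
        idx = int(np.argmax(deltas)) + 1
    else:
        raise ValueError(f"unknown method {method!r} (expected 'peak' or 'max_increase')")
    stage = curve.stages[idx]
    curve.transition_stage = stage
    return stage


def before_after_survival(
    scores: Sequence[SampleScore],
    transition: str,
    stage_order: Sequence[str],
    clinical: Sequence[SurvivalRecord],
) -> TransitionSurvival:
    """Log-rank comparison of samples up to and including the transition
    stage ("before") against samples from later stages ("after")."""
    order = list(stage_order)
    if transition not in order:
        raise ValueError(f"transition stage {transition!r} not in stage_order")
    cut = order.index(transition)
    by_id = {r.sample_id: r for r in clinical}
    before, after = [], []
    dropped = 0
    for s in scores:
        rec = by_id.get(s.sample_id)
        if rec is None:
            dropped += 1
            continue
        if order.index(s.stage) <= cut:
            before.append(rec)
        else:
            after.append(rec)
    if dropped:
        logger.warning("%d scored samples lack clinical records; dropped", dropped)
    if not before or not after:
        raise ValueError(
            f"empty survival group (before={len(before)}, after={len(after)}) "
            f"for transition at {transition!r}"
        )
    res = logrank_test(before, after)
    return TransitionSurvival(
        transition_stage=transition, before_n=len(before), after_n=len(after), result=res
    )
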