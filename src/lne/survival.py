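"""Kaplan-Meier estimation and the two-group log-rank test.

Deliberately self-contained (no survival-library dependency) so the
numerical behavior is fully specified here. Tie convention at equal
times: events precede censorings — both still count as at risk at that
time, and censored subjects leave the risk set afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KaplanMeierCurve",
    "LogRankResult",
    "km_curve",
    "logrank_test",
    "read_clinical",
    "write_clinical",
]


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError(f"survival time must be finite and > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event}")


@dataclass
class KaplanMeierCurve:
    """Product-limit step function; S(0) = 1, steps down at event times."""

    times: np.ndarray       # distinct event times, increasing
    survival: np.ndarray    # S(t) just after each event time
    n_records: int

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def restricted_mean(self, tau: float) -> float:
        """Area under the curve on [0, tau]."""
        rm, prev_t, prev_s = 0.0, 0.0, 1.0
        for t, s in zip(self.times, self.survival):
            if t >= tau:
                break
            rm += prev_s * (t - prev_t)
            prev_t, prev_s = t, s
        rm += prev_s * (tau - prev_t)
        return rm


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def _as_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_curve(records: Sequence[SurvivalRecord]) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator."""
    if not records:
        raise ValueError("empty record list")
    t, e = _as_arrays(records)
    event_times = np.unique(t[e == 1])
    surv = []
    s = 1.0
    for et in event_times:
        at_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
    return KaplanMeierCurve(times=event_times, survival=np.array(surv), n_records=len(records))


def logrank_test(group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]) -> LogRankResult:
    """Standard two-group log-rank chi-square test (1 df, asymptotic p)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ta, ea = _as_arrays(group_a)
    tb, eb = _as_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank statistic is 0", stacklevel=2)
        return LogRankResult(0.0, 1.0, (0.0, 0.0), (0.0, 0.0))

    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    event_times = np.unique(all_t[all_e == 1])

    o_a = e_a = o_b = e_b = 0.0
    var = 0.0
    for et in event_times:
        n_a = float((ta >= et).sum())
        n_b = float((tb >= et).sum())
        n = n_a + n_b
        d_a = float(((ta == et) & (ea == 1)).sum())
        d_b = float(((tb == et) & (eb == 1)).sum())
        d = d_a + d_b
        o_a += d_a
        o_b += d_b
        e_a += d * n_a / n
        e_b += d * n_b / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var <= 0:
        warnings.warn("degenerate risk sets; log-rank statistic is 0", stacklevel=2)
        return LogRankResult(0.0, 1.0, (o_a, o_b), (e_a, e_b))
    stat = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return LogRankResult(float(stat), p, (o_a, o_b), (e_a, e_b))


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Read a clinical table with columns sample_id, time, event.

    Time units (days/months) are passed through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clinical table not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks columns: {sorted(missing)}")
    return [
        SurvivalRecord(sample_id=str(r.sample_id), time=float(r.time), event=int(r.event))
        for r in df.itertuples()
    ]


def write_clinical(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")
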