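"""Sequential frequentist re-analysis over accrual: the P-value trajectory.

The effect estimate (OR, Wald CI, two-sided P) is recomputed at every look
``n = start_n, start_n + step, ...`` over the responders in accrual order,
producing the characteristic "dance" of the point estimate and P value as a
trial grows.  Crossings of the significance line are detected so that naive
"stop at the first significant look" behaviour can be studied explicitly.

:class:`SequentialORModel` is the object-oriented entry point; the
module-level functions (:func:`trajectory`, :func:`find_crossings`,
:func:`stop_at_first_crossing`) are the underlying functional API.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimate import EffectEstimate
from .records import TrialRecord, responder_arrays, read_trial_csv

INTO = "into_significance"
OUT = "out_of_significance"


@dataclass(frozen=True)
class TrajectoryPoint:
    """Effect estimate at one look of ``n`` responders."""

    n: int
    estimate: EffectEstimate
    significant: bool


@dataclass(frozen=True)
class Crossing:
    """A change of significance state at look ``n``."""

    n: int
    direction: str  # INTO or OUT


def look_schedule(n_responders: int, start_n: int, step: int) -> np.ndarray:
    """Looks at start_n, start_n+step, ..., always including the final n."""
    if start_n < 2:
        raise ValueError("start_n must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    looks = np.arange(start_n, n_responders + 1, step)
    if looks.size == 0 or looks[-1] != n_responders:
        if n_responders >= start_n:
            looks = np.append(looks, n_responders)
    return looks.astype(np.int64)


def _cells_at_looks(arm: np.ndarray, outcome: np.ndarray, looks: np.ndarray):
    """2x2 cell counts at each look, via cumulative sums over responders."""
    ei = np.cumsum(arm * outcome)[looks - 1].astype(float)
    n_i = np.cumsum(arm)[looks - 1].astype(float)
    ec = np.cumsum((1 - arm) * outcome)[looks - 1].astype(float)
    n_c = np.cumsum(1 - arm)[looks - 1].astype(float)
    return ei, n_i - ei, ec, n_c - ec


def trajectory_arrays(
    arm: np.ndarray,
    outcome: np.ndarray,
    start_n: int = 2,
    step: int = 1,
):
    """Vectorized trajectory over responder arrays.

    Returns ``(looks, log_or, se, p, corrected)`` numpy arrays; every look
    with a zero cell uses the Haldane–Anscombe +0.5 correction so the
    trajectory has no holes.  This is the shared fast path behind
    :func:`trajectory` and the Monte-Carlo operating-characteristics code.
    """
    looks = look_schedule(arm.size, start_n, step)
    if looks.size == 0:
        empty = np.empty(0)
        return looks, empty, empty, empty, np.empty(0, dtype=bool)
    ei, ni, ec, nc = _cells_at_looks(arm, outcome, looks)
    cells = np.stack([ei, ni, ec, nc])
    corrected = (cells == 0).any(axis=0)
    cells = cells + 0.5 * corrected
    ei, ni, ec, nc = cells
    log_or = np.log(ei) + np.log(nc) - np.log(ni) - np.log(ec)
    se = np.sqrt(1 / ei + 1 / ni + 1 / ec + 1 / nc)
    p = 2 * norm.sf(np.abs(log_or) / se)
    return looks, log_or, se, p, corrected


def trajectory(
    records: Sequence[TrialRecord],
    start_n: int = 2,
    step: int = 1,
    alpha: float = 0.05,
    ci_level: float = 0.95,
) -> list[TrajectoryPoint]:
    """Recompute the effect estimate at every look over accrual.

    One point per look ``n = start_n, start_n + step, ..., N`` (N always
    included); each point is exactly what a one-shot analysis of the first
    ``n`` responders would report.  Significance uses the strict inequality
    ``p < alpha``.  Fewer than ``start_n`` responders gives an empty
    trajectory with a warning.
    """
    from .estimate import odds_ratio
    from .records import ContingencyTable

    arm, outcome = responder_arrays(records)
    if arm.size < start_n:
        warnings.warn(
            f"only {arm.size} responders, fewer than start_n={start_n}: empty trajectory",
            stacklevel=2,
        )
        return []
    looks = look_schedule(arm.size, start_n, step)
    ei, ni, ec, nc = _cells_at_looks(arm, outcome, looks)
    points = []
    for k in range(looks.size):
        # same scalar code as a one-shot analysis, so recomputation at any
        # look reproduces the point bit-exactly
        table = ContingencyTable(int(ei[k]), int(ni[k]), int(ec[k]), int(nc[k]))
        est = odds_ratio(table, correction="haldane", ci_level=ci_level)
        points.append(TrajectoryPoint(int(looks[k]), est, est.p_value < alpha))
    return points


def find_crossings(points: Sequence[TrajectoryPoint]) -> list[Crossing]:
    """Looks at which the significance state changes.

    The first look is itself recorded as a crossing into significance if
    already significant; thereafter a crossing is recorded wherever the flag
    differs from the previous look, so directions alternate.
    """
    if not points:
        raise ValueError("trajectory is empty")
    crossings: list[Crossing] = []
    prev = False
    for pt in points:
        if pt.significant != prev:
            crossings.append(Crossing(pt.n, INTO if pt.significant else OUT))
            prev = pt.significant
    return crossings


def stop_at_first_crossing(points: Sequence[TrajectoryPoint]) -> TrajectoryPoint | None:
    """The naive peeking rule: the first significant look, or None."""
    if not points:
        raise ValueError("trajectory is empty")
    for pt in points:
        if pt.significant:
            return pt
    return None


def trajectory_frame(points: Sequence[TrajectoryPoint]) -> pd.DataFrame:
    """Trajectory as a DataFrame (n, or, ci_low, ci_high, p, significant)."""
    return pd.DataFrame(
        {
            "n": [p.n for p in points],
            "or": [p.estimate.or_value for p in points],
            "ci_low": [p.estimate.ci_low for p in points],
            "ci_high": [p.estimate.ci_high for p in points],
            "p": [p.estimate.p_value for p in points],
            "significant": [p.significant for p in points],
        }
    )


class SequentialORModel:
    """Sequential odds-ratio analysis of a two-arm binary trial.

    Parameters
    ----------
    records : sequence of TrialRecord
        Accrual-ordered trial records.
    start_n, step : int
        Look schedule over responders; defaults look at every responder
        from the second one, matching per-responder monitoring.
    alpha : float
        Two-sided significance threshold for the crossing analysis.

    Examples
    --------
    >>> res = SequentialORModel(records).fit()
    >>> res.crossings
    >>> res.summary()
    """

    def __init__(self, records, start_n: int = 2, step: int = 1, alpha: float = 0.05,
                 ci_level: float = 0.95):
        self.records = list(records)
        self.start_n = start_n
        self.step = step
        self.alpha = alpha
        self.ci_level = ci_level

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SequentialORModel":
        return cls(read_trial_csv(path), **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "SequentialORModel":
        """Build from a DataFrame in the trial CSV schema."""
        recs = [
            TrialRecord(
                int(row.accrual_index),
                str(row.arm),
                None if not bool(row.responded) else int(row.outcome),
                bool(row.responded),
            )
            for row in frame.itertuples()
        ]
        return cls(recs, **kwargs)

    def fit(self) -> "SequentialORResults":
        points = trajectory(self.records, self.start_n, self.step, self.alpha, self.ci_level)
        return SequentialORResults(self, points)


class SequentialORResults:
    """Fitted trajectory: per-look estimates, crossings, stopping behaviour."""

    def __init__(self, model: SequentialORModel, points: list[TrajectoryPoint]):
        self.model = model
        self.points = points

    @property
    def crossings(self) -> list[Crossing]:
        return find_crossings(self.points) if self.points else []

    @property
    def first_significant(self) -> TrajectoryPoint | None:
        return stop_at_first_crossing(self.points) if self.points else None

    @property
    def final(self) -> TrajectoryPoint | None:
        return self.points[-1] if self.points else None

    def frame(self) -> pd.DataFrame:
        return trajectory_frame(self.points)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)

    def plot(self, ax=None, events: Sequence[int] = ()):  # pragma: no cover - thin wrapper
        from .plotting import plot_trajectory

        return plot_trajectory(self.points, alpha=self.model.alpha, events=events)

    def summary(self) -> str:
        """Plain-text summary in the style of a fitted-model report."""
        lines = ["Sequential odds-ratio analysis", "=" * 38]
        lines.append(f"looks: {len(self.points)}  (start_n={self.model.start_n}, "
                     f"step={self.model.step}, alpha={self.model.alpha})")
        if self.points:
            f = self.final
            lines.append(
                f"final look n={f.n}: OR {f.estimate.or_value:.3f} "
                f"({f.estimate.ci_level:.0%} CI {f.estimate.ci_low:.3f}-{f.estimate.ci_high:.3f}; "
                f"P={f.estimate.p_value:.3g})"
            )
            cr = self.crossings
            lines.append(f"significance-line crossings: {len(cr)}")
            first = self.first_significant
            if first is not None:
                lines.append(f"first significant look: n={first.n} "
                             f"(OR {first.estimate.or_value:.3f}, P={first.estimate.p_value:.3g})")
            else:
                lines.append("never significant over the schedule")
        else:
            lines.append("empty trajectory (too few responders)")
        return "\n".join(lines)
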