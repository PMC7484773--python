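"""Figure grammar for sequential monitoring.

Two layouts: the two-panel frequentist trajectory (OR with its CI band on
top, P value below, reference lines at OR=1 and p=alpha) and the
three-panel Bayesian monitoring trace (median OR; probability of success;
probability of futility; reference lines at OR=1 and the decision
thresholds).  Optional vertical event lines mark interim analyses or other
accrual milestones.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt

from .bayes import DecisionRule, MonitoringResult
from .sequential import TrajectoryPoint


def plot_trajectory(
    points: Sequence[TrajectoryPoint],
    alpha: float = 0.05,
    events: Sequence[int] = (),
    title: str | None = None,
):
    """Two stacked panels: OR (log scale) with CI band, and two-sided P."""
    fig, (ax_or, ax_p) = plt.subplots(2, 1, sharex=True, figsize=(8, 6))
    if points:
        n = [pt.n for pt in points]
        ax_or.fill_between(
            n,
            [pt.estimate.ci_low for pt in points],
            [pt.estimate.ci_high for pt in points],
            alpha=0.25,
            lw=0,
        )
        ax_or.plot(n, [pt.estimate.or_value for pt in points], lw=1.2)
        ax_p.plot(n, [pt.estimate.p_value for pt in points], lw=1.2)
    ax_or.axhline(1.0, color="k", lw=0.8, ls="--")
    ax_or.set_yscale("log")
    ax_or.set_ylabel("odds ratio")
    ax_p.axhline(alpha, color="k", lw=0.8, ls="--")
    ax_p.set_ylim(0, 1)
    ax_p.set_ylabel("two-sided P")
    ax_p.set_xlabel("responders")
    for ax in (ax_or, ax_p):
        for ev in events:
            ax.axvline(ev, color="grey", lw=0.8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_monitoring(
    result: MonitoringResult,
    rule: DecisionRule = DecisionRule(),
    events: Sequence[int] = (),
    title: str | None = None,
):
    """Three stacked panels: median OR, P(success), P(futility)."""
    fig, (ax_or, ax_s, ax_f) = plt.subplots(3, 1, sharex=True, figsize=(8, 8))
    if result.looks:
        n = [l.n for l in result.looks]
        ax_or.plot(n, [l.posterior.median_or for l in result.looks], lw=1.2)
        ax_s.plot(n, [l.posterior.prob_success for l in result.looks], lw=1.2)
        ax_f.plot(n, [l.posterior.prob_futility for l in result.looks], lw=1.2)
    ax_or.axhline(1.0, color="k", lw=0.8, ls="--")
    ax_or.set_yscale("log")
    ax_or.set_ylabel("median OR")
    ax_s.axhline(rule.success_prob_threshold, color="k", lw=0.8, ls="--")
    ax_s.set_ylim(0, 1)
    ax_s.set_ylabel("P(success)")
    ax_f.axhline(rule.futility_prob_threshold, color="k", lw=0.8, ls="--")
    ax_f.set_ylim(0, 1)
    ax_f.set_ylabel("P(futility)")
    ax_f.set_xlabel("responders")
    for ax in (ax_or, ax_s, ax_f):
        for ev in events:
            ax.axvline(ev, color="grey", lw=0.8)
    if result.stop_n is not None:
        for ax in (ax_or, ax_s, ax_f):
            ax.axvline(result.stop_n, color="firebrick", lw=1.0)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
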