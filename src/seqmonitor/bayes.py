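"""Bayesian group sequential monitoring of the odds ratio.

Inference is on the log odds-ratio scale under a *skeptical* normal prior —
by default mean 0 (OR 1) and SD 0.2 — encoding a strong a-priori belief that
the intervention has little or no effect, which accumulating data must
overcome.  At every look the posterior yields:

* ``prob_success``  = P(OR > success bound), default bound OR = 1;
* ``prob_futility`` = P(futility_low < OR < futility_high), default interval
  (1/1.25, 1.25), a practical-equivalence region.

The trial stops for success when prob_success exceeds its threshold
(default 0.95, strict inequality) and for futility when prob_futility does;
success is checked first when both fire at the same look.  Because the
posterior equals the prior before any data accrue, neither criterion can
fire at the outset: prob_success starts at exactly 0.5 and prob_futility at
about 0.735 under the defaults.

Two posterior engines are provided.  The primary ``conjugate`` method is the
normal–normal precision-weighted update applied to the Wald summary of the
log-OR (fast, deterministic).  The ``grid`` method evaluates the exact
two-binomial likelihood — a uniform prior on the control event probability,
the skeptical prior on the log-OR — on a 2-D grid and marginalizes; it
serves both as a user-selectable engine and as the internal accuracy oracle
for the conjugate approximation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, binom

from .estimate import EffectEstimate, odds_ratio
from .records import TrialRecord, ContingencyTable, responder_arrays, read_trial_csv
from .sequential import trajectory_arrays, look_schedule

CONTINUE = "continue"
STOP_SUCCESS = "stop_success"
STOP_FUTILITY = "stop_futility"


@dataclass(frozen=True)
class SkepticalPrior:
    """Normal prior on the log odds ratio; mean 0 means 'no effect'."""

    mean: float = 0.0
    sd: float = 0.2

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")

    def summary(self, rule: "DecisionRule | None" = None) -> "PosteriorSummary":
        """The decision state before any data: the prior itself."""
        rule = rule or DecisionRule()
        return _normal_summary(self.mean, self.sd, rule, method="conjugate")


@dataclass(frozen=True)
class DecisionRule:
    """Success/futility stopping criteria on the OR scale."""

    success_or_bound: float = 1.0
    success_prob_threshold: float = 0.95
    futility_low: float = 1 / 1.25
    futility_high: float = 1.25
    futility_prob_threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.futility_low < self.futility_high:
            raise ValueError("futility interval must satisfy 0 < low < high")
        for t in (self.success_prob_threshold, self.futility_prob_threshold):
            if not 0 < t < 1:
                raise ValueError("probability thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class PosteriorSummary:
    """Normal-form posterior over the log-OR with decision probabilities."""

    mean: float
    sd: float
    median_or: float
    prob_success: float
    prob_futility: float
    method: str

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class Look:
    n: int
    posterior: PosteriorSummary
    decision: str


@dataclass(frozen=True)
class MonitoringResult:
    """Per-look decisions and the stopping record (if any)."""

    looks: tuple[Look, ...]
    stop_n: int | None = None
    stop_reason: str | None = None


def _normal_summary(mean: float, sd: float, rule: DecisionRule, method: str) -> PosteriorSummary:
    prob_success = float(norm.sf(math.log(rule.success_or_bound), loc=mean, scale=sd))
    prob_futility = float(
        norm.cdf(math.log(rule.futility_high), loc=mean, scale=sd)
        - norm.cdf(math.log(rule.futility_low), loc=mean, scale=sd)
    )
    return PosteriorSummary(
        mean=mean,
        sd=sd,
        median_or=math.exp(mean),
        prob_success=prob_success,
        prob_futility=prob_futility,
        method=method,
    )


def posterior_conjugate(
    estimate: EffectEstimate,
    prior: SkepticalPrior = SkepticalPrior(),
    rule: DecisionRule = DecisionRule(),
) -> PosteriorSummary:
    """Normal–normal update of the prior with the Wald log-OR summary.

    Posterior precision is the sum of the prior and data precisions and the
    posterior mean is the precision-weighted average of the prior mean and
    the observed log-OR — the usual conjugate shrinkage, so the posterior
    mean always sits between prior and data.
    """
    se = estimate.se_log_or
    if not (se > 0 and math.isfinite(se)):
        raise ValueError("estimate must have finite positive se_log_or")
    prior_prec = 1 / prior.sd**2
    data_prec = 1 / se**2
    post_var = 1 / (prior_prec + data_prec)
    post_mean = post_var * (prior_prec * prior.mean + data_prec * estimate.log_or)
    return _normal_summary(post_mean, math.sqrt(post_var), rule, method="conjugate")


@dataclass(frozen=True)
class GridSpec:
    """Resolution and extent of the exact grid posterior."""

    n_p: int = 401          # control event probability grid points
    n_log_or: int = 1201    # log-OR grid points
    tail_sd: float = 8.0    # half-width in SD units around prior and likelihood
    norm_tol: float = 1e-6  # admissible posterior mass on the grid boundary


class GridResolutionError(RuntimeError):
    """The grid leaks posterior mass past its edges; use a finer/wider grid."""


def posterior_grid(
    table: ContingencyTable,
    prior: SkepticalPrior = SkepticalPrior(),
    rule: DecisionRule = DecisionRule(),
    grid: GridSpec = GridSpec(),
) -> PosteriorSummary:
    """Exact-likelihood posterior over the log-OR on a 2-D grid.

    The control event probability p_c gets a uniform prior; the log-OR gets
    the skeptical prior.  The joint posterior over (p_c, log-OR) is
    evaluated on a rectangular grid, marginalized to the log-OR, and
    summarized by its mean, SD, and the rule's decision probabilities.
    """
    if table.total <= 0:
        raise ValueError("table has no observations")
    ei, ni, ec, nc = table.cells()
    n_i, n_c = ei + ni, ec + nc

    # log-OR grid wide enough for both the prior and the likelihood bulk
    wald = odds_ratio(table, correction="haldane")
    lo = min(prior.mean - grid.tail_sd * prior.sd, wald.log_or - grid.tail_sd * wald.se_log_or)
    hi = max(prior.mean + grid.tail_sd * prior.sd, wald.log_or + grid.tail_sd * wald.se_log_or)
    beta = np.linspace(lo, hi, grid.n_log_or)
    # midpoint grid for p_c avoids the 0/1 endpoints
    pc = (np.arange(grid.n_p) + 0.5) / grid.n_p

    odds_c = pc / (1 - pc)
    # p_i implied by (p_c, beta): odds_i = exp(beta) * odds_c
    odds_i = np.exp(beta)[:, None] * odds_c[None, :]
    pi = odds_i / (1 + odds_i)

    log_lik = (
        binom.logpmf(ec, n_c, pc)[None, :]
        + binom.logpmf(ei, n_i, pi)
        + norm.logpdf(beta, prior.mean, prior.sd)[:, None]
    )
    log_lik -= log_lik.max()
    joint = np.exp(log_lik)
    marg = joint.sum(axis=1)
    total = marg.sum()
    if total <= 0:
        raise GridResolutionError("posterior mass vanished on the grid; widen or refine it")
    marg /= total
    edge_mass = marg[0] + marg[-1]
    if edge_mass > grid.norm_tol:
        raise GridResolutionError(
            f"posterior mass {edge_mass:.2e} on the log-OR grid boundary exceeds "
            f"{grid.norm_tol:.0e}; advise a wider or finer grid"
        )

    mean = float(np.sum(beta * marg))
    sd = float(math.sqrt(np.sum((beta - mean) ** 2 * marg)))
    # centred-mass CDF with linear interpolation between grid points, so a
    # threshold falling on or between points splits its mass correctly
    cdf_at_points = np.cumsum(marg) - 0.5 * marg

    def cdf(x: float) -> float:
        return float(np.interp(x, beta, cdf_at_points, left=0.0, right=1.0))

    prob_success = 1.0 - cdf(math.log(rule.success_or_bound))
    prob_futility = cdf(math.log(rule.futility_high)) - cdf(math.log(rule.futility_low))
    return PosteriorSummary(
        mean=mean,
        sd=sd,
        median_or=math.exp(mean),
        prob_success=prob_success,
        prob_futility=prob_futility,
        method="grid",
    )


def _conjugate_arrays(log_or, se, prior: SkepticalPrior, rule: DecisionRule):
    """Vectorized conjugate update over trajectory arrays."""
    prior_prec = 1 / prior.sd**2
    data_prec = 1 / np.asarray(se) ** 2
    post_var = 1 / (prior_prec + data_prec)
    post_mean = post_var * (prior_prec * prior.mean + data_prec * np.asarray(log_or))
    post_sd = np.sqrt(post_var)
    ps = norm.sf((math.log(rule.success_or_bound) - post_mean) / post_sd)
    pf = norm.cdf((math.log(rule.futility_high) - post_mean) / post_sd) - norm.cdf(
        (math.log(rule.futility_low) - post_mean) / post_sd
    )
    return post_mean, post_sd, ps, pf


def monitor(
    records: Sequence[TrialRecord],
    prior: SkepticalPrior = SkepticalPrior(),
    rule: DecisionRule = DecisionRule(),
    start_n: int = 2,
    step: int = 1,
    method: str = "conjugate",
) -> MonitoringResult:
    """Run the group sequential monitor over accrual.

    At each look the posterior is computed (Haldane-corrected Wald summary
    feeding the conjugate update, so monitoring is defined from ``start_n``)
    and the decision rule is evaluated with strict inequalities; looks cease
    at the first stop.  ``method="grid"`` recomputes each look with the
    exact grid posterior (slower).
    """
    if method not in ("conjugate", "grid"):
        raise ValueError("method must be 'conjugate' or 'grid'")
    arm, outcome = responder_arrays(records)
    if arm.size < start_n:
        return MonitoringResult(looks=())
    looks_idx, log_or, se, _, _ = trajectory_arrays(arm, outcome, start_n, step)

    if method == "conjugate":
        mean, sd, ps, pf = _conjugate_arrays(log_or, se, prior, rule)
        summaries = [
            PosteriorSummary(float(mean[k]), float(sd[k]), float(np.exp(mean[k])),
                             float(ps[k]), float(pf[k]), "conjugate")
            for k in range(looks_idx.size)
        ]
    else:
        from .records import tabulate

        summaries = [
            posterior_grid(tabulate(records, int(n)), prior, rule) for n in looks_idx
        ]

    out: list[Look] = []
    stop_n = None
    stop_reason = None
    for k, n in enumerate(looks_idx):
        s = summaries[k]
        if s.prob_success > rule.success_prob_threshold:
            decision = STOP_SUCCESS
        elif s.prob_futility > rule.futility_prob_threshold:
            decision = STOP_FUTILITY
        else:
            decision = CONTINUE
        out.append(Look(int(n), s, decision))
        if decision != CONTINUE:
            stop_n = int(n)
            stop_reason = decision
            break
    return MonitoringResult(looks=tuple(out), stop_n=stop_n, stop_reason=stop_reason)


def monitoring_frame(result: MonitoringResult) -> pd.DataFrame:
    """Monitoring trace as a DataFrame (n, median_or, probs, decision)."""
    return pd.DataFrame(
        {
            "n": [l.n for l in result.looks],
            "median_or": [l.posterior.median_or for l in result.looks],
            "prob_success": [l.posterior.prob_success for l in result.looks],
            "prob_futility": [l.posterior.prob_futility for l in result.looks],
            "decision": [l.decision for l in result.looks],
        }
    )


class BayesianMonitorModel:
    """Bayesian group sequential monitor for a two-arm binary trial.

    Wraps :func:`monitor`; ``fit()`` returns a
    :class:`BayesianMonitorResults` carrying the per-look posteriors,
    decisions, and stopping record.
    """

    def __init__(
        self,
        records,
        prior: SkepticalPrior = SkepticalPrior(),
        rule: DecisionRule = DecisionRule(),
        start_n: int = 2,
        step: int = 1,
        method: str = "conjugate",
    ):
        self.records = list(records)
        self.prior = prior
        self.rule = rule
        self.start_n = start_n
        self.step = step
        self.method = method

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BayesianMonitorModel":
        return cls(read_trial_csv(path), **kwargs)

    def fit(self) -> "BayesianMonitorResults":
        res = monitor(self.records, self.prior, self.rule, self.start_n, self.step, self.method)
        return BayesianMonitorResults(self, res)


class BayesianMonitorResults:
    def __init__(self, model: BayesianMonitorModel, result: MonitoringResult):
        self.model = model
        self.result = result

    @property
    def looks(self) -> tuple[Look, ...]:
        return self.result.looks

    @property
    def stop_n(self) -> int | None:
        return self.result.stop_n

    @property
    def stop_reason(self) -> str | None:
        return self.result.stop_reason

    def frame(self) -> pd.DataFrame:
        return monitoring_frame(self.result)

    def to_csv(self, path) -> None:
        self.frame().to_csv(path, index=False)

    def plot(self, events: Sequence[int] = ()):  # pragma: no cover - thin wrapper
        from .plotting import plot_monitoring

        return plot_monitoring(self.result, rule=self.model.rule, events=events)

    def summary(self) -> str:
        r = self.result
        lines = ["Bayesian group sequential monitor", "=" * 38]
        lines.append(
            f"prior: normal(mean={self.model.prior.mean}, sd={self.model.prior.sd}) on log-OR"
        )
        rule = self.model.rule
        lines.append(
            f"rule: P(OR>{rule.success_or_bound})>{rule.success_prob_threshold} success; "
            f"P({rule.futility_low:.3g}<OR<{rule.futility_high:.3g})>"
            f"{rule.futility_prob_threshold} futility"
        )
        lines.append(f"looks evaluated: {len(r.looks)}")
        if r.looks:
            last = r.looks[-1]
            lines.append(
                f"last look n={last.n}: median OR {last.posterior.median_or:.3f}, "
                f"P(success)={last.posterior.prob_success:.3f}, "
                f"P(futility)={last.posterior.prob_futility:.3f}"
            )
        if r.stop_n is not None:
            lines.append(f"stopped at n={r.stop_n}: {r.stop_reason}")
        else:
            lines.append("no stopping criterion fired; continue recruitment")
        return "\n".join(lines)
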