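"""Operating characteristics of stopping strategies, by Monte Carlo.

Simulates many trials from a known-truth configuration and analyzes each
one three ways on *identical data* (paired design, per-rep seeds derived
deterministically from the base seed):

* naive peeking — declare an effect if the two-sided Wald P ever drops
  below alpha over the look schedule;
* a single fixed look at the final n — the textbook test whose type I
  error is the nominal alpha;
* the Bayesian group sequential monitor — stop for success/futility by
  posterior probabilities under the skeptical prior.

Under a null configuration the naive crossing rate exhibits the familiar
multiplicity inflation (many looks, many chances to cross), while the
fixed look sits near alpha and the skeptical prior holds the Bayesian
false-success rate down on the very same data streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import SkepticalPrior, DecisionRule, _conjugate_arrays
from .records import responder_arrays
from .sequential import trajectory_arrays
from .simulate import SyntheticTrialConfig, generate


@dataclass(frozen=True)
class OCResult:
    """Monte-Carlo stopping-strategy rates over ``reps`` simulated trials."""

    reps: int
    naive_cross_rate: float
    fixed_look_rate: float
    bayes_false_success_rate: float
    bayes_futility_rate: float
    mean_stop_n: float | None
    seeds: int
    per_rep: pd.DataFrame = field(repr=False, compare=False)

    def summary(self) -> str:
        lines = ["Operating characteristics", "=" * 38]
        lines.append(f"replicates: {self.reps} (base seed {self.seeds})")
        lines.append(f"naive peeking ever-crossing rate : {self.naive_cross_rate:.4f}")
        lines.append(f"single final-look rejection rate : {self.fixed_look_rate:.4f}")
        lines.append(f"Bayesian stop-for-success rate   : {self.bayes_false_success_rate:.4f}")
        lines.append(f"Bayesian stop-for-futility rate  : {self.bayes_futility_rate:.4f}")
        if self.mean_stop_n is not None:
            lines.append(f"mean Bayesian stopping look      : {self.mean_stop_n:.1f}")
        return "\n".join(lines)


def run_oc(
    config: SyntheticTrialConfig,
    prior: SkepticalPrior = SkepticalPrior(),
    rule: DecisionRule = DecisionRule(),
    alpha: float = 0.05,
    start_n: int = 20,
    step: int = 1,
    reps: int = 1000,
    base_seed: int = 0,
) -> OCResult:
    """Paired Monte-Carlo comparison of naive peeking vs Bayesian monitoring.

    Each replicate regenerates the trial with seed ``base_seed + rep`` and
    is analyzed by every strategy on the same data.  Rates are fractions of
    replicates; ``mean_stop_n`` averages the stopping look over replicates
    where the Bayesian monitor stopped (None if it never stopped).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rows = []
    stop_ns = []
    for rep in range(reps):
        cfg = SyntheticTrialConfig(
            n=config.n,
            p_control=config.p_control,
            true_or=config.true_or,
            allocation=config.allocation,
            attrition_prob=config.attrition_prob,
            drift=config.drift,
            seed=base_seed + rep,
        )
        arm, outcome = responder_arrays(generate(cfg))
        looks, log_or, se, p, _ = trajectory_arrays(arm, outcome, start_n=start_n, step=step)
        if looks.size == 0:
            raise ValueError("no looks: responders fall below start_n")
        naive_cross = bool((p < alpha).any())
        fixed_sig = bool(p[-1] < alpha)
        _, _, ps, pf = _conjugate_arrays(log_or, se, prior, rule)
        succ_hits = np.flatnonzero(ps > rule.success_prob_threshold)
        fut_hits = np.flatnonzero(pf > rule.futility_prob_threshold)
        first_succ = succ_hits[0] if succ_hits.size else None
        first_fut = fut_hits[0] if fut_hits.size else None
        if first_succ is not None and (first_fut is None or first_succ <= first_fut):
            stop_reason, stop_k = "stop_success", first_succ
        elif first_fut is not None:
            stop_reason, stop_k = "stop_futility", first_fut
        else:
            stop_reason, stop_k = None, None
        stop_n = int(looks[stop_k]) if stop_k is not None else None
        if stop_n is not None:
            stop_ns.append(stop_n)
        rows.append(
            {
                "rep": rep,
                "seed": base_seed + rep,
                "naive_cross": naive_cross,
                "fixed_look_significant": fixed_sig,
                "bayes_stop": stop_reason,
                "bayes_stop_n": stop_n,
                "final_p": float(p[-1]),
            }
        )
    frame = pd.DataFrame(rows)
    n_succ = int((frame["bayes_stop"] == "stop_success").sum())
    n_fut = int((frame["bayes_stop"] == "stop_futility").sum())
    return OCResult(
        reps=reps,
        naive_cross_rate=float(frame["naive_cross"].mean()),
        fixed_look_rate=float(frame["fixed_look_significant"].mean()),
        bayes_false_success_rate=n_succ / reps,
        bayes_futility_rate=n_fut / reps,
        mean_stop_n=float(np.mean(stop_ns)) if stop_ns else None,
        seeds=base_seed,
        per_rep=frame,
    )
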