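"""Synthetic two-arm binary trials with known truth.

The generator emulates the design of a simple parallel-group trial: equal
(or user-set) probability randomization to intervention/control, a Bernoulli
endpoint at a stated control event probability, a true odds ratio applied on
the odds scale, sequential accrual, optional missing-completely-at-random
follow-up attrition, and optional regime drift — piecewise changes of the
control event probability over accrual (e.g. seasonal differences), with
the OR held constant so the estimand is stable across regimes.

Every stochastic quantity is driven by a single integer seed through
``numpy.random.default_rng``, so a configuration reproduces its trial
bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .records import TrialRecord, CONTROL, INTERVENTION


def implied_intervention_probability(p_control: float, true_or: float) -> float:
    """Event probability in the intervention arm implied by (p_control, OR).

    Standard odds mapping: ``odds_i = OR * odds_c``, then back to a
    probability; exact, so ``odds(p_i)/odds(p_c) == OR``.
    """
    if not 0 < p_control < 1:
        raise ValueError("p_control must lie strictly between 0 and 1")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    odds_c = p_control / (1 - p_control)
    odds_i = true_or * odds_c
    return odds_i / (1 + odds_i)


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Design parameters of a synthetic trial.

    drift, when given, is a sequence of ``(end_accrual_index, p_control)``
    pairs whose end indices partition ``1..n`` (the last end must equal n);
    each segment uses its own control event probability while the true OR is
    held fixed on the odds scale.
    """

    n: int
    p_control: float = 0.25
    true_or: float = 1.0
    allocation: float = 0.5
    attrition_prob: float = 0.0
    drift: tuple[tuple[int, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("config field n must be >= 1")
        if not 0 < self.p_control < 1:
            raise ValueError("config field p_control must lie in (0, 1)")
        if self.true_or <= 0:
            raise ValueError("config field true_or must be positive")
        if not 0 < self.allocation < 1:
            raise ValueError("config field allocation must lie in (0, 1)")
        if not 0 <= self.attrition_prob < 1:
            raise ValueError("config field attrition_prob must lie in [0, 1)")
        if self.drift is not None:
            ends = [e for e, _ in self.drift]
            if ends != sorted(ends) or len(set(ends)) != len(ends):
                raise ValueError("config field drift: segment ends must be strictly increasing")
            if ends[-1] != self.n:
                raise ValueError("config field drift: segments must partition 1..n")
            for _, p in self.drift:
                if not 0 < p < 1:
                    raise ValueError("config field drift: each p_control must lie in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTrialConfig":
        d = json.loads(text)
        if d.get("drift") is not None:
            d["drift"] = tuple((int(e), float(p)) for e, p in d["drift"])
        return cls(**d)


def _p_control_per_record(config: SyntheticTrialConfig) -> np.ndarray:
    p = np.full(config.n, config.p_control)
    if config.drift is not None:
        start = 0
        for end, seg_p in config.drift:
            p[start:end] = seg_p
            start = end
    return p


def generate(config: SyntheticTrialConfig) -> list[TrialRecord]:
    """Generate an accrual-ordered synthetic trial.

    Arms are i.i.d. Bernoulli(allocation), outcomes Bernoulli at the arm's
    (possibly drifting) event probability, and response status i.i.d.
    Bernoulli(1 - attrition_prob), independent of arm and outcome.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    arm = rng.random(n) < config.allocation  # True = intervention
    pc = _p_control_per_record(config)
    odds_c = pc / (1 - pc)
    odds_i = config.true_or * odds_c
    pi = odds_i / (1 + odds_i)
    p_event = np.where(arm, pi, pc)
    outcome = rng.random(n) < p_event
    responded = rng.random(n) >= config.attrition_prob
    return [
        TrialRecord(
            accrual_index=i + 1,
            arm=INTERVENTION if arm[i] else CONTROL,
            outcome=int(outcome[i]) if responded[i] else None,
            responded=bool(responded[i]),
        )
        for i in range(n)
    ]


# Presets sized like the two motivating studies (a school-based smoking
# cessation text-messaging trial with 535 recruits and high follow-up
# attrition, and a nested alcohol text-message experiment with 560
# participants and an immediately observed outcome).  Event probabilities
# and ORs are synthetic package defaults — NOT estimates of any real trial.
PRESETS: dict[str, SyntheticTrialConfig] = {
    "smoking_trial": SyntheticTrialConfig(
        n=535, p_control=0.25, true_or=1.8, allocation=0.5, attrition_prob=0.2, seed=20
    ),
    "alcohol_message_experiment": SyntheticTrialConfig(
        n=560, p_control=0.30, true_or=1.1, allocation=0.5, attrition_prob=0.0, seed=21
    ),
}


def generate_trial_like_paper(preset: str) -> tuple[list[TrialRecord], SyntheticTrialConfig]:
    """A preset synthetic trial mimicking one of the motivating designs.

    Only the sample size and design are mimicked; outcomes are synthetic.
    """
    try:
        config = PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return generate(config), config
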