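"""Bootstrap trial extension: "what if we had recruited more people?"

An observed trial is extended by drawing new pseudo-participants with
replacement from its own responders, then re-running the sequential
analysis on the lengthened accrual stream.  Because the resampled
participants share the source sample's effect, any nontrivial odds ratio
eventually drags the P value below any fixed threshold as the extension
grows — statistical significance is a function of sample size, which is
precisely what the exercise demonstrates.

Resampling is of (arm, outcome) pairs by default; the stratified option
draws outcomes within each arm under alternating allocation, keeping arm
sizes from drifting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .records import TrialRecord, CONTROL, INTERVENTION, responders
from .sequential import TrajectoryPoint, trajectory


@dataclass(frozen=True)
class ExtensionConfig:
    """How many pseudo-participants to add and how to draw them."""

    n_extra: int
    seed: int = 0
    stratify_by_arm: bool = False

    def __post_init__(self) -> None:
        if self.n_extra < 0:
            raise ValueError("n_extra must be nonnegative")


def extend(records: Sequence[TrialRecord], config: ExtensionConfig) -> list[TrialRecord]:
    """Append ``n_extra`` records resampled with replacement from responders.

    New accrual indices continue after the original maximum; the original
    records are returned unchanged, in order, ahead of the extension.  Only
    responding records enter the sampling pool, and every drawn record is a
    responder by construction.
    """
    records = list(records)
    pool = responders(records)
    if not pool:
        raise ValueError("no responding records to sample from")
    if config.n_extra == 0:
        return records
    rng = np.random.default_rng(config.seed)
    next_index = max(r.accrual_index for r in records) + 1

    extra: list[TrialRecord] = []
    if not config.stratify_by_arm:
        draws = rng.integers(0, len(pool), size=config.n_extra)
        for k, j in enumerate(draws):
            src = pool[j]
            extra.append(TrialRecord(next_index + k, src.arm, src.outcome, True))
    else:
        by_arm = {
            CONTROL: [r for r in pool if r.arm == CONTROL],
            INTERVENTION: [r for r in pool if r.arm == INTERVENTION],
        }
        for arm, sub in by_arm.items():
            if not sub:
                raise ValueError(f"stratified extension needs at least one responder in {arm}")
        # alternating allocation keeps the extension balanced between arms
        for k in range(config.n_extra):
            arm = INTERVENTION if k % 2 == 0 else CONTROL
            sub = by_arm[arm]
            src = sub[rng.integers(0, len(sub))]
            extra.append(TrialRecord(next_index + k, arm, src.outcome, True))
    return records + extra


def extended_trajectory(
    records: Sequence[TrialRecord],
    config: ExtensionConfig,
    start_n: int = 2,
    step: int = 1,
    alpha: float = 0.05,
) -> list[TrajectoryPoint]:
    """Sequential analysis of the bootstrap-extended trial.

    Equals ``trajectory(extend(records, config), ...)``; points at looks not
    exceeding the original responder count are identical to the unextended
    trajectory, since the extension only appends.
    """
    return trajectory(extend(records, config), start_n=start_n, step=step, alpha=alpha)
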