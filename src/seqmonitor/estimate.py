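"""Frequentist effect estimation for a 2x2 table: odds ratio, Wald CI, Wald P.

All inference is carried out on the log odds-ratio scale.  The standard
error is the usual square root of the sum of reciprocal cell counts; the CI
is log-symmetric (so the geometric mean of its bounds recovers the point
estimate) and the two-sided P value comes from the normal approximation to
the log-OR.  When any cell is zero the Haldane–Anscombe correction adds 0.5
to every cell so that the estimate and its SE stay finite from the very
first looks of a trial.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

from scipy.stats import norm

from .records import ContingencyTable


class ZeroCellError(ZeroDivisionError):
    """The OR or its SE is undefined because of an empty cell."""


@dataclass(frozen=True)
class EffectEstimate:
    """Odds ratio with Wald interval and two-sided P at a single look."""

    or_value: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    ci_level: float
    p_value: float
    corrected: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def wald_ci(log_or: float, se_log_or: float, level: float = 0.95) -> tuple[float, float]:
    """Log-symmetric Wald interval on the OR scale.

    Bounds are ``exp(log_or -/+ z * se_log_or)`` with z the standard normal
    quantile at (1+level)/2.
    """
    if se_log_or < 0:
        raise ValueError("se_log_or must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must lie strictly between 0 and 1")
    z = norm.ppf((1 + level) / 2)
    return math.exp(log_or - z * se_log_or), math.exp(log_or + z * se_log_or)


def wald_p(log_or: float, se_log_or: float) -> float:
    """Two-sided P from the normal approximation to the log-OR.

    A degenerate SE of zero yields P=0 for any nonzero log-OR and P=1 at
    the null point itself.
    """
    if se_log_or < 0:
        raise ValueError("se_log_or must be nonnegative")
    if se_log_or == 0:
        return 1.0 if log_or == 0 else 0.0
    return float(2 * norm.sf(abs(log_or) / se_log_or))


def odds_ratio(
    table: ContingencyTable,
    correction: str = "haldane",
    ci_level: float = 0.95,
) -> EffectEstimate:
    """Sample odds ratio of a 2x2 table with Wald CI and two-sided P.

    Parameters
    ----------
    table : ContingencyTable
        Events/non-events by intervention/control.
    correction : {"haldane", "none"}
        With ``"haldane"``, 0.5 is added to every cell when (and only when)
        some cell is zero, and the estimate is flagged ``corrected``.  With
        ``"none"``, a zero cell raises :class:`ZeroCellError`.
    ci_level : float
        Confidence level of the Wald interval.
    """
    if correction not in ("haldane", "none"):
        raise ValueError("correction must be 'haldane' or 'none'")
    if table.total <= 0:
        raise ValueError("table has no observations")
    cells = table.cells()
    corrected = False
    if any(c == 0 for c in cells):
        if correction == "none":
            raise ZeroCellError("zero cell: odds ratio undefined without correction")
        cells = tuple(c + 0.5 for c in cells)
        corrected = True
    ei, ni, ec, nc = cells
    log_or = math.log(ei * nc) - math.log(ni * ec)
    se = math.sqrt(1 / ei + 1 / ni + 1 / ec + 1 / nc)
    lo, hi = wald_ci(log_or, se, ci_level)
    return EffectEstimate(
        or_value=math.exp(log_or),
        log_or=log_or,
        se_log_or=se,
        ci_low=lo,
        ci_high=hi,
        ci_level=ci_level,
        p_value=wald_p(log_or, se),
        corrected=corrected,
    )
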