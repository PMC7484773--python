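"""Trial records: the accrual-ordered participant table behind every analysis.

A two-arm trial is represented as an ordered sequence of :class:`TrialRecord`
entries, one per randomized participant, sorted by accrual order.  Analyses
index "looks" by *responders* — participants who provided follow-up data —
so non-responders never consume a look slot.  The on-disk format is a plain
CSV with columns ``accrual_index,arm,outcome,responded``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

CONTROL = "control"
INTERVENTION = "intervention"
_ARMS = (CONTROL, INTERVENTION)

CSV_COLUMNS = ("accrual_index", "arm", "outcome", "responded")

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


class TrialCSVError(ValueError):
    """Malformed trial CSV; the message names the offending row or column."""


@dataclass(frozen=True)
class TrialRecord:
    """One randomized participant.

    Parameters
    ----------
    accrual_index : int
        1-based position in accrual order; unique within a trial.
    arm : str
        ``"control"`` or ``"intervention"``.
    outcome : int or None
        Binary endpoint (1 = event, e.g. abstinence or link press).  Defined
        only when ``responded`` is True; None otherwise.
    responded : bool
        Whether the participant provided follow-up data.
    """

    accrual_index: int
    arm: str
    outcome: int | None
    responded: bool = True

    def __post_init__(self) -> None:
        if self.accrual_index < 1:
            raise ValueError("accrual_index must be a positive integer")
        if self.arm not in _ARMS:
            raise ValueError(f"unknown arm label {self.arm!r}; expected one of {_ARMS}")
        if self.responded:
            if self.outcome not in (0, 1):
                raise ValueError("outcome must be 0 or 1 for a responding record")
        elif self.outcome is not None:
            raise ValueError("outcome is undefined for a non-responding record")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of events/non-events by intervention/control at one look."""

    events_i: float
    nonevents_i: float
    events_c: float
    nonevents_c: float

    def __post_init__(self) -> None:
        for name in ("events_i", "nonevents_i", "events_c", "nonevents_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.events_i + self.nonevents_i + self.events_c + self.nonevents_c

    def cells(self) -> tuple[float, float, float, float]:
        return (self.events_i, self.nonevents_i, self.events_c, self.nonevents_c)

    def swapped_arms(self) -> "ContingencyTable":
        """The same table with the arm labels exchanged."""
        return ContingencyTable(self.events_c, self.nonevents_c, self.events_i, self.nonevents_i)


def _parse_bool(text: str, row_no: int) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise TrialCSVError(f"row {row_no}: cannot parse responded value {text!r}")


def read_trial_csv(path) -> list[TrialRecord]:
    """Read a trial CSV, validating schema and returning accrual-sorted records.

    The file must carry the header ``accrual_index,arm,outcome,responded``;
    ``outcome`` may be empty when ``responded`` is false.  Errors name the
    offending row (1-based, counting the header as row 1).
    """
    records: list[TrialRecord] = []
    seen: set[int] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TrialCSVError("empty file: missing header") from None
        header = [h.strip() for h in header]
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise TrialCSVError(f"missing columns: {', '.join(missing)}")
        idx = {c: header.index(c) for c in CSV_COLUMNS}
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            try:
                accrual = int(row[idx["accrual_index"]])
            except (ValueError, IndexError):
                raise TrialCSVError(f"row {row_no}: bad accrual_index") from None
            if accrual in seen:
                raise TrialCSVError(f"row {row_no}: duplicate accrual_index {accrual}")
            seen.add(accrual)
            arm = row[idx["arm"]].strip()
            if arm not in _ARMS:
                raise TrialCSVError(f"row {row_no}: unknown arm label {arm!r}")
            responded = _parse_bool(row[idx["responded"]], row_no)
            raw_outcome = row[idx["outcome"]].strip()
            outcome: int | None
            if responded:
                if raw_outcome not in ("0", "1"):
                    raise TrialCSVError(f"row {row_no}: outcome must be 0 or 1 for a responder")
                outcome = int(raw_outcome)
            else:
                if raw_outcome not in ("", "NA", "na", "."):
                    raise TrialCSVError(
                        f"row {row_no}: outcome must be empty for a non-responder"
                    )
                outcome = None
            records.append(TrialRecord(accrual, arm, outcome, responded))
    records.sort(key=lambda r: r.accrual_index)
    return records


def write_trial_csv(path, records: Iterable[TrialRecord]) -> None:
    """Write records in the trial CSV schema (round-trips with the reader)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.accrual_index,
                    r.arm,
                    "" if r.outcome is None else r.outcome,
                    "true" if r.responded else "false",
                ]
            )


def responders(records: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Responding records in accrual order (the look index set)."""
    return [r for r in records if r.responded]


def responder_arrays(records: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(arm, outcome) integer arrays over responders, accrual ordered.

    arm is 1 for intervention, 0 for control.  Internal fast path shared by
    trajectory and monitoring code.
    """
    resp = responders(records)
    arm = np.fromiter((1 if r.arm == INTERVENTION else 0 for r in resp), dtype=np.int64, count=len(resp))
    out = np.fromiter((r.outcome for r in resp), dtype=np.int64, count=len(resp))
    return arm, out


def tabulate(records: Sequence[TrialRecord], n: int) -> ContingencyTable:
    """2x2 table from the first ``n`` responders in accrual order.

    Non-responders are skipped and do not consume look slots.
    """
    resp = responders(records)
    if n < 1:
        raise ValueError("look size n must be >= 1")
    if n > len(resp):
        raise ValueError(f"look size n={n} exceeds responder count (maximum {len(resp)})")
    ei = ni = ec = nc = 0
    for r in resp[:n]:
        if r.arm == INTERVENTION:
            if r.outcome == 1:
                ei += 1
            else:
                ni += 1
        else:
            if r.outcome == 1:
                ec += 1
            else:
                nc += 1
    return ContingencyTable(ei, ni, ec, nc)
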