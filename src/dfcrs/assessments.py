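"""Scoring of the six patient-reported tinnitus instruments.

All six instruments are sums over validated items:

========  =====  ============  =========
scale     items  item range    total
========  =====  ============  =========
THI       25     {0, 2, 4}     0-100
HADS      14     0..3          A,D: 0-21
AIS       8      0..3          0-24
FTQ       17     {0, 1}        0-17
TCS       13     0..4          0-52
VAS       1      0..10         0-10
========  =====  ============  =========

HADS splits into a 7-item anxiety (HADS-A) and a 7-item depression (HADS-D)
subscale. The shipped anxiety-item assignment (items 1,3,5,7,9,11,13 in
1-based order) is the conventional alternating layout of the published
instrument, configurable for alternative orderings.

Missing items are an error by default; an opt-in prorating mode rescales the
sum of answered items to the full item count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "INSTRUMENTS",
    "DEFAULT_HADS_ANXIETY_INDICES",
    "ItemResponses",
    "ScaleScore",
    "ItemValidationError",
    "score",
    "score_thi",
    "score_hads",
    "score_ais",
    "score_ftq",
    "score_tcs",
    "score_vas",
    "validate_severity",
    "score_responses_frame",
]

#: instrument -> (item count, allowed item values)
INSTRUMENTS: dict[str, tuple[int, frozenset[int]]] = {
    "THI": (25, frozenset({0, 2, 4})),
    "HADS": (14, frozenset(range(4))),
    "AIS": (8, frozenset(range(4))),
    "FTQ": (17, frozenset({0, 1})),
    "TCS": (13, frozenset(range(5))),
    "VAS": (1, frozenset(range(11))),
}

#: Zero-based positions of the anxiety items in a 14-item HADS response
#: (the conventional alternating A/D ordering; a convention, not a trial claim).
DEFAULT_HADS_ANXIETY_INDICES = frozenset({0, 2, 4, 6, 8, 10, 12})

TIMEPOINTS = ("T0", "T1", "T2", "T3")


class ItemValidationError(ValueError):
    """An item response fails the instrument's count or range rules."""


@dataclass(frozen=True)
class ItemResponses:
    """Ordered item responses for one administration of one instrument.

    Items may be ``None`` only when scored with ``prorate=True``.
    """

    instrument: str
    items: tuple[int | None, ...]

    def __post_init__(self) -> None:
        if self.instrument not in INSTRUMENTS:
            raise ItemValidationError(
                f"unknown instrument {self.instrument!r}; "
                f"expected one of {sorted(INSTRUMENTS)}"
            )
        object.__setattr__(self, "items", tuple(self.items))
        n, allowed = INSTRUMENTS[self.instrument]
        if len(self.items) != n:
            raise ItemValidationError(
                f"{self.instrument} requires {n} items, got {len(self.items)}"
            )
        for i, v in enumerate(self.items):
            if v is None:
                continue
            if not isinstance(v, (int,)) or isinstance(v, bool) or v not in allowed:
                raise ItemValidationError(
                    f"{self.instrument} item {i}: value {v!r} not in "
                    f"{sorted(allowed)}"
                )


@dataclass(frozen=True)
class ScaleScore:
    """A scored instrument: total points plus any subscales."""

    instrument: str
    total: float
    subscales: dict[str, float] = field(default_factory=dict)
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")


def _sum_items(resp: ItemResponses, prorate: bool) -> float:
    answered = [v for v in resp.items if v is not None]
    n_missing = len(resp.items) - len(answered)
    if n_missing and not prorate:
        raise ItemValidationError(
            f"{resp.instrument}: {n_missing} missing item(s); "
            "enable prorate=True to rescale"
        )
    if not answered:
        raise ItemValidationError(f"{resp.instrument}: all items missing")
    total = float(sum(answered))
    if n_missing:
        total *= len(resp.items) / len(answered)
    return total


def score_thi(responses: ItemResponses, prorate: bool = False) -> ScaleScore:
    """Tinnitus Handicap Inventory: 25 items scored 0/2/4, total 0-100."""
    if responses.instrument != "THI":
        raise ItemValidationError("score_thi expects THI responses")
    return ScaleScore("THI", _sum_items(responses, prorate))


def score_hads(
    responses: ItemResponses,
    anxiety_item_indices: frozenset[int] | set[int] = DEFAULT_HADS_ANXIETY_INDICES,
    prorate: bool = False,
) -> ScaleScore:
    """HADS: 14 items 0-3; anxiety/depression subscales of 7 items each."""
    if responses.instrument != "HADS":
        raise ItemValidationError("score_hads expects HADS responses")
    anx = frozenset(anxiety_item_indices)
    if len(anx) != 7 or not anx <= set(range(14)):
        raise ItemValidationError(
            "anxiety_item_indices must be 7 distinct indices in 0..13, "
            f"got {sorted(anx)}"
        )
    def subtotal(idx: frozenset[int]) -> float:
        vals = [responses.items[i] for i in sorted(idx)]
        answered = [v for v in vals if v is not None]
        if len(answered) < len(vals) and not prorate:
            raise ItemValidationError("HADS: missing item(s); enable prorate")
        if not answered:
            raise ItemValidationError("HADS: empty subscale")
        t = float(sum(answered))
        if len(answered) < len(vals):
            t *= len(vals) / len(answered)
        return t

    a = subtotal(anx)
    d = subtotal(frozenset(range(14)) - anx)
    return ScaleScore("HADS", a + d, subscales={"A": a, "D": d})


def score_ais(responses: ItemResponses, prorate: bool = False) -> ScaleScore:
    """Athens Insomnia Scale: 8 items 0-3, total 0-24."""
    if responses.instrument != "AIS":
        raise ItemValidationError("score_ais expects AIS responses")
    return ScaleScore("AIS", _sum_items(responses, prorate))


def score_ftq(responses: ItemResponses, prorate: bool = False) -> ScaleScore:
    """Fear of Tinnitus Questionnaire: 17 binary items, total 0-17."""
    if responses.instrument != "FTQ":
        raise ItemValidationError("score_ftq expects FTQ responses")
    return ScaleScore("FTQ", _sum_items(responses, prorate))


def score_tcs(responses: ItemResponses, prorate: bool = False) -> ScaleScore:
    """Tinnitus Catastrophizing Scale: 13 items 0-4, total 0-52."""
    if responses.instrument != "TCS":
        raise ItemValidationError("score_tcs expects TCS responses")
    return ScaleScore("TCS", _sum_items(responses, prorate))


def score_vas(responses: ItemResponses) -> ScaleScore:
    """Visual Analog Scale: single validated integer 0-10, passed through."""
    if responses.instrument != "VAS":
        raise ItemValidationError("score_vas expects VAS responses")
    return ScaleScore("VAS", _sum_items(responses, prorate=False))


_SCORERS = {
    "THI": score_thi,
    "HADS": score_hads,
    "AIS": score_ais,
    "FTQ": score_ftq,
    "TCS": score_tcs,
    "VAS": lambda r, prorate=False: score_vas(r),
}


def score(responses: ItemResponses, **kwargs) -> ScaleScore:
    """Dispatch to the scorer for ``responses.instrument``."""
    return _SCORERS[responses.instrument](responses, **kwargs)


_ROMAN = {"I": "I", "II": "II", "III": "III", "IV": "IV"}
_UNICODE_ROMAN = {"Ⅰ": "I", "Ⅱ": "II", "Ⅲ": "III", "Ⅳ": "IV"}
_NUMERIC = {1: "I", 2: "II", 3: "III", 4: "IV"}


def validate_severity(grade) -> str:
    """Normalise a tinnitus severity grade token to one of I/II/III/IV.

    Accepts Roman numerals (ASCII or Unicode), integers 1-4 and their string
    forms; anything else is rejected.
    """
    if isinstance(grade, str):
        g = grade.strip().upper()
        if g in _ROMAN:
            return _ROMAN[g]
        if g in _UNICODE_ROMAN:
            return _UNICODE_ROMAN[g]
        if g.isdigit() and int(g) in _NUMERIC:
            return _NUMERIC[int(g)]
    elif isinstance(grade, int) and not isinstance(grade, bool):
        if grade in _NUMERIC:
            return _NUMERIC[grade]
    raise ItemValidationError(f"unknown severity grade {grade!r}")


# ---------------------------------------------------------------------------
# CSV plumbing: long responses in, tidy scores out
# ---------------------------------------------------------------------------

def score_responses_frame(df: pd.DataFrame, prorate: bool = False) -> pd.DataFrame:
    """Score a long-form response table.

    Input columns: subject_id, timepoint, instrument, item_index (0-based),
    value. Returns tidy scores: subject_id, timepoint, instrument, subscale
    ('' for the total), score.
    """
    required = {"subject_id", "timepoint", "instrument", "item_index", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"response table lacks columns: {sorted(missing)}")
    rows = []
    for (sid, tp, inst), sub in df.groupby(
        ["subject_id", "timepoint", "instrument"], sort=True
    ):
        n_items = INSTRUMENTS[inst][0]
        items: list[int | None] = [None] * n_items
        for _, r in sub.iterrows():
            idx = int(r["item_index"])
            if not 0 <= idx < n_items:
                raise ItemValidationError(
                    f"{inst} item index {idx} out of range for {sid}/{tp}"
                )
            items[idx] = int(r["value"])
        sc = score(ItemResponses(inst, tuple(items)), prorate=prorate) \
            if inst != "VAS" else score_vas(ItemResponses(inst, tuple(items)))
        rows.append(
            {"subject_id": sid, "timepoint": tp, "instrument": inst,
             "subscale": "", "score": sc.total}
        )
        for name, val in sc.subscales.items():
            rows.append(
                {"subject_id": sid, "timepoint": tp, "instrument": inst,
                 "subscale": name, "score": val}
            )
    return pd.DataFrame(rows)
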