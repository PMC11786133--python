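"""Audiograms, tinnitus profiles, pure-tone averages and trial eligibility.

The pure-tone average (PTA) used throughout is the arithmetic mean of the
air-conduction thresholds at 500, 1000, 2000 and 4000 Hz, and eligibility
follows the enrolment rules of the source trial: adults (age >= 18) whose
worse-ear PTA does not exceed 55 dB HL and who carry none of the exclusion
diagnoses (pulsatile or objective tinnitus, otosclerosis, Meniere disease,
acute sudden sensorineural hearing loss, severe systemic disease).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "STANDARD_FREQUENCIES_HZ",
    "PTA_FREQUENCIES_HZ",
    "EXCLUSION_FLAGS",
    "Audiogram",
    "TinnitusProfile",
    "EligibilityVerdict",
    "MissingFrequencyError",
    "compute_pta",
    "check_eligibility",
    "worse_ear_pta",
    "read_audiograms_csv",
    "write_audiograms_csv",
    "audiogram_to_json",
    "audiogram_from_json",
]

#: Audiometric test frequencies covered by the intake audiogram (Hz).
STANDARD_FREQUENCIES_HZ = (125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)

#: Frequencies entering the pure-tone average (Hz).
PTA_FREQUENCIES_HZ = (500.0, 1000.0, 2000.0, 4000.0)

#: Recognised exclusion diagnoses.
EXCLUSION_FLAGS = frozenset(
    {
        "pulsatile",
        "objective",
        "otosclerosis",
        "meniere",
        "sudden_snhl_acute",
        "severe_systemic",
    }
)

#: Maximum worse-ear PTA for enrolment (dB HL).
PTA_ELIGIBILITY_LIMIT_DB_HL = 55.0

#: Minimum age for enrolment (years).
MIN_AGE_YEARS = 18.0

_THRESHOLD_RANGE_DB_HL = (-10.0, 120.0)

_SEVERITY_GRADES = ("I", "II", "III", "IV")


class MissingFrequencyError(ValueError):
    """A frequency required for the requested computation is absent."""


@dataclass(frozen=True)
class Audiogram:
    """Per-ear air-conduction thresholds.

    Parameters
    ----------
    ear : {"left", "right"}
    frequencies : tuple of float
        Test frequencies in Hz, strictly ascending, drawn from the standard
        audiometric set (125 Hz - 8 kHz).
    thresholds : tuple of float
        One threshold in dB HL per frequency, each within [-10, 120].
    """

    ear: str
    frequencies: tuple[float, ...]
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError(f"ear must be 'left' or 'right', got {self.ear!r}")
        freqs = tuple(float(f) for f in self.frequencies)
        thrs = tuple(float(t) for t in self.thresholds)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "thresholds", thrs)
        if len(freqs) != len(thrs):
            raise ValueError(
                f"{len(freqs)} frequencies but {len(thrs)} thresholds"
            )
        if len(freqs) == 0:
            raise ValueError("audiogram needs at least one frequency")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError(f"frequencies must be strictly ascending: {freqs}")
        unknown = set(freqs) - set(STANDARD_FREQUENCIES_HZ)
        if unknown:
            raise ValueError(
                f"non-standard audiometric frequencies: {sorted(unknown)}"
            )
        lo, hi = _THRESHOLD_RANGE_DB_HL
        for f, t in zip(freqs, thrs):
            if not (lo <= t <= hi):
                raise ValueError(
                    f"threshold {t} dB HL at {f} Hz outside [{lo}, {hi}]"
                )

    def threshold_at(self, frequency_hz: float) -> float:
        """Threshold (dB HL) at an exact test frequency."""
        try:
            idx = self.frequencies.index(float(frequency_hz))
        except ValueError:
            raise MissingFrequencyError(
                f"audiogram ({self.ear}) has no threshold at {frequency_hz} Hz"
            ) from None
        return self.thresholds[idx]


@dataclass(frozen=True)
class TinnitusProfile:
    """Tinnitus characteristics collected at intake."""

    pitch_hz: float
    location: str = "unilateral"
    course_months: float = 0.0
    status: str = "continued"
    severity_grade: str = "I"

    def __post_init__(self) -> None:
        if not (0.0 < self.pitch_hz < 20000.0):
            raise ValueError(
                f"pitch_hz must lie in (0, 20000), got {self.pitch_hz}"
            )
        if self.location not in ("unilateral", "in_head", "bilateral"):
            raise ValueError(f"unknown tinnitus location {self.location!r}")
        if self.course_months < 0:
            raise ValueError("course_months must be >= 0")
        if self.status not in ("continued", "intermittent"):
            raise ValueError(f"unknown tinnitus status {self.status!r}")
        if self.severity_grade not in _SEVERITY_GRADES:
            raise ValueError(
                f"severity_grade must be one of {_SEVERITY_GRADES}, "
                f"got {self.severity_grade!r}"
            )


@dataclass(frozen=True)
class EligibilityVerdict:
    """Outcome of the enrolment check; ``reasons`` lists every failed rule."""

    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:
        return self.eligible


def compute_pta(audiogram: Audiogram) -> float:
    """Pure-tone average: mean threshold at 500, 1000, 2000 and 4000 Hz.

    Raises
    ------
    MissingFrequencyError
        If any of the four PTA frequencies is absent from the audiogram.
    """
    vals = [audiogram.threshold_at(f) for f in PTA_FREQUENCIES_HZ]
    return sum(vals) / len(vals)


def worse_ear_pta(left: Audiogram, right: Audiogram) -> float:
    """PTA of the worse (higher-PTA) ear; ties give the common value."""
    return max(compute_pta(left), compute_pta(right))


def check_eligibility(
    age: float,
    worse_ear_pta: float,
    exclusion_flags: frozenset[str] | set[str] = frozenset(),
) -> EligibilityVerdict:
    """Apply the trial enrolment rules.

    Eligible iff age >= 18, worse-ear PTA <= 55 dB HL (the boundary itself is
    eligible: "no more than") and no exclusion diagnosis is present. The
    verdict carries every failed rule, not just the first.
    """
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    flags = frozenset(exclusion_flags)
    unknown = flags - EXCLUSION_FLAGS
    if unknown:
        raise ValueError(f"unknown exclusion flags: {sorted(unknown)}")
    reasons: list[str] = []
    if age < MIN_AGE_YEARS:
        reasons.append(f"age {age} < {MIN_AGE_YEARS:g} years")
    if worse_ear_pta > PTA_ELIGIBILITY_LIMIT_DB_HL:
        reasons.append(
            f"worse-ear PTA {worse_ear_pta:g} dB HL > "
            f"{PTA_ELIGIBILITY_LIMIT_DB_HL:g} dB HL"
        )
    for flag in sorted(flags):
        reasons.append(f"exclusion diagnosis: {flag}")
    return EligibilityVerdict(eligible=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# I/O: long-form CSV (ear, frequency_hz, threshold_db_hl) and compact JSON
# ---------------------------------------------------------------------------

def read_audiograms_csv(path) -> dict[str, Audiogram]:
    """Read audiograms from CSV with columns ear, frequency_hz, threshold_db_hl.

    Returns a mapping ear -> Audiogram for the ears present.
    """
    df = pd.read_csv(path)
    required = {"ear", "frequency_hz", "threshold_db_hl"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"audiogram CSV lacks columns: {sorted(missing)}")
    out: dict[str, Audiogram] = {}
    for ear, sub in df.groupby("ear"):
        sub = sub.sort_values("frequency_hz")
        out[str(ear)] = Audiogram(
            ear=str(ear),
            frequencies=tuple(sub["frequency_hz"].astype(float)),
            thresholds=tuple(sub["threshold_db_hl"].astype(float)),
        )
    return out


def write_audiograms_csv(audiograms, path) -> None:
    """Write one or more audiograms to the long CSV schema."""
    if isinstance(audiograms, Audiogram):
        audiograms = [audiograms]
    rows = [
        {"ear": a.ear, "frequency_hz": f, "threshold_db_hl": t}
        for a in audiograms
        for f, t in zip(a.frequencies, a.thresholds)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def audiogram_to_json(audiogram: Audiogram) -> str:
    """Compact JSON form (frequency -> threshold map) used by the CLI."""
    return json.dumps(
        {
            "ear": audiogram.ear,
            "thresholds_db_hl": {
                f"{f:g}": t
                for f, t in zip(audiogram.frequencies, audiogram.thresholds)
            },
        }
    )


def audiogram_from_json(text: str) -> Audiogram:
    obj = json.loads(text)
    items = sorted(
        ((float(f), float(t)) for f, t in obj["thresholds_db_hl"].items())
    )
    return Audiogram(
        ear=obj["ear"],
        frequencies=tuple(f for f, _ in items),
        thresholds=tuple(t for _, t in items),
    )
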