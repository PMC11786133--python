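import numpy as np
import pandas as pd
import pytest

from dfcrs import AudioSignal, Cohort, SimulationConfig, generate_cohort


def make_tone(freq_hz, duration_s=2.0, fs=44100.0, amplitude=0.1, channels=1):
    """Pure sine test fixture, small amplitude so the limiter stays inactive."""
    t = np.arange(int(round(duration_s * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    if channels == 2:
        x = np.stack([x, x], axis=1)
    return AudioSignal(x, fs)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort shared by read-only tests."""
    return generate_cohort(SimulationConfig(), seed=20240917)


@pytest.fixture()
def tiny_cohort_frame():
    """Hand-sized 6-subject cohort for oracle comparisons."""
    subjects = pd.DataFrame({
        "subject_id": [f"P{i}" for i in range(6)],
        "arm": ["DFCRS"] * 3 + ["UM"] * 3,
        "gender": ["male", "female"] * 3,
        "age_years": [30, 40, 50, 35, 45, 55],
        "location": ["unilateral"] * 6,
        "course_months": [6, 12, 24, 6, 12, 24],
        "status": ["continued"] * 6,
        "severity_grade": ["II"] * 6,
        "pitch_hz": [4000.0] * 6,
        "daily_listen_hours": [2.0] * 6,
        "outcome": ["relief", "worsened", "disappeared", "", "", ""],
    })
    rows = []
    for i, sid in enumerate(subjects["subject_id"]):
        for j, (tp, day) in enumerate(zip(["T0", "T1", "T2", "T3"],
                                          [0, 30, 60, 90])):
            thi = 60.0 - 10.0 * j - 2.0 * i
            rows.append({"subject_id": sid, "timepoint": tp, "day": day,
                         "thi": thi, "hads_a": 5, "hads_d": 4, "ais": 6,
                         "ftq": 7, "tcs": 20, "vas": 5})
    return Cohort(subjects=subjects, long=pd.DataFrame(rows))
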