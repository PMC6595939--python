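import numpy as np
import pandas as pd
import pytest

import chronowear as cw

RECORD_COLS = ["subject_id", "anchor_date", "onset_axis", "wake_axis",
               "waso_min", "nap_min", "steps"]


def make_records(rows):
    """Records frame from (sid, date, onset_clock_h, wake_clock_h, waso,
    nap, steps) tuples, with clock hours converted onto the night axis."""
    df = pd.DataFrame(rows, columns=["subject_id", "anchor_date",
                                     "onset_clock", "wake_clock",
                                     "waso_min", "nap_min", "steps"])
    return pd.DataFrame({
        "subject_id": df["subject_id"],
        "anchor_date": pd.to_datetime(df["anchor_date"]),
        "onset_axis": cw.clock_to_axis(df["onset_clock"].to_numpy(float)),
        "wake_axis": cw.clock_to_axis(df["wake_clock"].to_numpy(float)),
        "waso_min": df["waso_min"].astype(float),
        "nap_min": df["nap_min"].astype(float),
        "steps": df["steps"].astype(float),
    })


def schedule_records(sid, n_weeks=2, work=(0.25, 7.0), free=(0.25, 7.0),
                     waso_work=0.0, waso_free=None, nap=0.0, steps=8000,
                     start="2017-04-02"):
    """Constant-schedule records: ``work``/``free`` are (onset, wake) clock
    hours; weeks start on the given Sunday."""
    waso_free = waso_work if waso_free is None else waso_free
    dates = pd.date_range(start, periods=7 * n_weeks, freq="D")
    rows = []
    for d in dates:
        onset, wake = (free if d.weekday() in cw.FREE_WEEKDAYS else work)
        waso = waso_free if d.weekday() in cw.FREE_WEEKDAYS else waso_work
        rows.append((sid, d.date().isoformat(), onset, wake, waso, nap, steps))
    return make_records(rows)


@pytest.fixture(scope="session")
def default_sim():
    """One default-parameter cohort shared by the statistical checks."""
    return cw.simulate(cw.SimConfig(n_subjects=5000, n_weeks=4, seed=20070))


@pytest.fixture(scope="session")
def default_summaries(default_sim):
    return cw.build_summaries(default_sim.records, default_sim.subjects)
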