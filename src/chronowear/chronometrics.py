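"""Per-subject chronobiology statistics.

Computes, for each subject, the quantities that operationalise chronotype
and social jetlag from longitudinal sleep records:

* **MSW / MSF** — mean mid-sleep point on work / free nights (clock hours
  after midnight).  The mid-sleep point of one night is the clock time
  halfway between sleep onset and final awakening; WASO is ignored for
  mid-sleep and subtracted only from durations.
* **SDw / SDf** — mean nocturnal sleep duration (time in bed minus WASO)
  on work / free nights, in hours.
* **SJL** — social jetlag, the signed difference MSF − MSW in hours.
  Negative SJL means earlier mid-sleep on free days.
* **MSFsc** — mid-sleep on free days corrected for the sleep debt
  accumulated on work days::

      MSFsc = MSF − 0.5 · [SDf − (5·SDw + 2·SDf) / 7]

  evaluated within each complete Sunday-anchored week and averaged over
  weeks.  The correction is applied unconditionally, exactly as written
  (also when SDf < SDw), so SDf = SDw implies MSFsc = MSF identically.
* **Chronotype** — early (MSFsc < 3:00), intermediate (3:00–5:00,
  boundaries inclusive), late (> 5:00).
* **Nap group** — zero (mean daily nap 0 min), short (0 < nap ≤ 30 min),
  long (> 30 min).

All clock-time averaging happens on the noon-anchored night axis (see
:mod:`chronowear.sleep_records`), where every episode lies in a single
linear window, so arithmetic means are exact and no circular statistics
are needed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sleep_records import (axis_to_clock, complete_weeks, is_free_night,
                            nocturnal_sleep_min)

logger = logging.getLogger("chronowear")

CHRONOTYPE_CUTOFFS = (3.0, 5.0)  # clock hours after midnight
NAP_LONG_MIN = 30.0              # minutes
MIN_WEEKS_DEFAULT = 2

SUMMARY_CSV_COLUMNS = ["subject_id", "msw", "msf", "sdw", "sdf", "sjl_h",
                       "msfsc_h", "chronotype", "nap_group", "mean_nap_min",
                       "total_sleep_work_min", "total_sleep_free_min"]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def mid_sleep(onset_axis, wake_axis):
    """Mid-sleep point of a nocturnal episode, in clock hours after midnight.

    Inputs are night-axis hours (noon-anchored) and must satisfy
    ``0 < onset < wake < 24``.  Scalar in, scalar out; arrays broadcast.
    """
    o = np.asarray(onset_axis, dtype=float)
    w = np.asarray(wake_axis, dtype=float)
    if np.any(~((o > 0) & (o < w) & (w < 24))):
        raise ValueError("require 0 < onset_axis < wake_axis < 24")
    mid = ((o + w) / 2.0 - 12.0) % 24.0
    return float(mid) if np.ndim(onset_axis) == 0 and np.ndim(wake_axis) == 0 else mid


def sleep_debt_corrected(msf_h, sdw_h, sdf_h):
    """MSFsc correction: MSF − 0.5·[SDf − (5·SDw + 2·SDf)/7], hours.

    Evaluated in the algebraically identical form
    MSF − (5/14)·(SDf − SDw) so that SDf = SDw leaves MSF unchanged to
    machine precision.  Applied unconditionally, also when SDf < SDw.
    """
    msf = np.asarray(msf_h, dtype=float)
    sdw = np.asarray(sdw_h, dtype=float)
    sdf = np.asarray(sdf_h, dtype=float)
    out = msf - 0.5 * (5.0 / 7.0) * (sdf - sdw)
    return float(out) if out.ndim == 0 else out


def classify_chronotype(msfsc_h, cutoffs=CHRONOTYPE_CUTOFFS):
    """early / intermediate / late by MSFsc; boundaries go to intermediate."""
    early, late = cutoffs
    x = np.asarray(msfsc_h, dtype=float)
    out = np.select([np.isnan(x), x < early, x > late],
                    [None, "early", "late"], default="intermediate")
    return out.item() if x.ndim == 0 else out


def classify_nap_group(mean_nap_min):
    """zero (0 min) / short (0 < nap ≤ 30 min) / long (> 30 min)."""
    x = np.asarray(mean_nap_min, dtype=float)
    if np.any(x < 0):
        raise ValueError("mean nap duration must be non-negative")
    out = np.select([x == 0, x > NAP_LONG_MIN], ["zero", "long"],
                    default="short")
    return out.item() if x.ndim == 0 else out


# ---------------------------------------------------------------------------
# weekly MSFsc
# ---------------------------------------------------------------------------

def msfsc_week(week: pd.DataFrame) -> float:
    """MSFsc of one complete week (7 nights, 5 work + 2 free)."""
    if len(week) != 7 or week["anchor_date"].nunique() != 7:
        raise ValueError("msfsc_week requires a complete 7-night week")
    free = is_free_night(week["anchor_date"])
    if int(free.sum()) != 2:
        raise ValueError("complete week must contain exactly 2 free nights")
    mid = mid_sleep(week["onset_axis"].to_numpy(), week["wake_axis"].to_numpy())
    dur_h = nocturnal_sleep_min(week).to_numpy() / 60.0
    free_np = free.to_numpy()
    msf = mid[free_np].mean()
    sdw = dur_h[~free_np].mean()
    sdf = dur_h[free_np].mean()
    return sleep_debt_corrected(msf, sdw, sdf)


def msfsc_subject(weekly_values, min_weeks: int = MIN_WEEKS_DEFAULT) -> float:
    """Subject MSFsc = mean of weekly MSFsc values; NaN below ``min_weeks``."""
    vals = np.asarray(list(weekly_values), dtype=float)
    if vals.size < min_weeks:
        return float("nan")
    return float(vals.mean())


def _weekly_msfsc_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, week_start) MSFsc on the night axis, vectorised."""
    cw = complete_weeks(records)
    if cw.empty:
        return pd.DataFrame(columns=["subject_id", "week_start", "msfsc_axis"])
    cw = cw.copy()
    cw["is_free"] = is_free_night(cw["anchor_date"])
    cw["mid_axis"] = (cw["onset_axis"] + cw["wake_axis"]) / 2.0
    cw["dur_h"] = nocturnal_sleep_min(cw) / 60.0
    g = cw.groupby(["subject_id", "week_start", "is_free"])
    agg = g.agg(mid=("mid_axis", "mean"), dur=("dur_h", "mean")).unstack("is_free")
    msf_axis = agg[("mid", True)]
    sdw = agg[("dur", False)]
    sdf = agg[("dur", True)]
    msfsc_axis = sleep_debt_corrected(msf_axis, sdw, sdf)
    out = pd.Series(msfsc_axis, index=msf_axis.index,
                    name="msfsc_axis").reset_index()
    return out


# ---------------------------------------------------------------------------
# subject summaries
# ---------------------------------------------------------------------------

def build_summaries(records: pd.DataFrame, subjects: pd.DataFrame | None = None,
                    min_weeks: int = MIN_WEEKS_DEFAULT,
                    cutoffs=CHRONOTYPE_CUTOFFS,
                    require_age_for_msfsc: bool = True) -> pd.DataFrame:
    """Build the per-subject summary table from validated records.

    Subjects lacking either work or free nights get NaN MSW/MSF/SJL and are
    thereby absent from SJL analyses.  MSFsc requires at least ``min_weeks``
    complete weeks and (when a subject table with ages is supplied and
    ``require_age_for_msfsc``) a known age; otherwise MSFsc and chronotype
    are missing, mirroring the smaller chronotype cohort.

    Besides the canonical columns the table carries night-axis schedule
    means (``onset_work_axis`` …) and overall means (``nocturnal_min``,
    ``steps_mean``) used by the cohort-level analyses.
    """
    rec = records.copy()
    rec["is_free"] = is_free_night(rec["anchor_date"])
    rec["mid_axis"] = (rec["onset_axis"] + rec["wake_axis"]) / 2.0
    rec["sleep_min"] = nocturnal_sleep_min(rec)
    rec["total_min"] = rec["sleep_min"] + rec["nap_min"]

    by_type = (rec.groupby(["subject_id", "is_free"])
               .agg(mid=("mid_axis", "mean"),
                    sleep=("sleep_min", "mean"),
                    onset=("onset_axis", "mean"),
                    wake=("wake_axis", "mean"),
                    total=("total_min", "mean"),
                    n=("mid_axis", "size"))
               .unstack("is_free"))
    for col in ["mid", "sleep", "onset", "wake", "total", "n"]:
        for flag in (False, True):
            if (col, flag) not in by_type.columns:
                by_type[(col, flag)] = np.nan

    overall = rec.groupby("subject_id").agg(
        mean_nap_min=("nap_min", "mean"),
        nocturnal_min=("sleep_min", "mean"),
        steps_mean=("steps", "mean"),
        n_nights=("mid_axis", "size"))

    out = pd.DataFrame(index=by_type.index)
    msw_axis = by_type[("mid", False)]
    msf_axis = by_type[("mid", True)]
    out["msw_axis"] = msw_axis
    out["msf_axis"] = msf_axis
    out["msw"] = axis_to_clock(msw_axis)
    out["msf"] = axis_to_clock(msf_axis)
    out["sdw"] = by_type[("sleep", False)] / 60.0
    out["sdf"] = by_type[("sleep", True)] / 60.0
    out["sjl_h"] = msf_axis - msw_axis
    out["onset_work_axis"] = by_type[("onset", False)]
    out["wake_work_axis"] = by_type[("wake", False)]
    out["onset_free_axis"] = by_type[("onset", True)]
    out["wake_free_axis"] = by_type[("wake", True)]
    out["total_sleep_work_min"] = by_type[("total", False)]
    out["total_sleep_free_min"] = by_type[("total", True)]
    out = out.join(overall)

    weekly = _weekly_msfsc_table(rec)
    if not weekly.empty:
        wk = weekly.groupby("subject_id")["msfsc_axis"].agg(["mean", "size"])
        msfsc_axis = wk["mean"].where(wk["size"] >= min_weeks)
        out["n_weeks"] = wk["size"].reindex(out.index).fillna(0).astype(int)
        out["msfsc_h"] = axis_to_clock(msfsc_axis.reindex(out.index))
    else:
        out["n_weeks"] = 0
        out["msfsc_h"] = np.nan

    out = out.reset_index()
    if subjects is not None:
        meta = subjects.set_index("subject_id")
        if require_age_for_msfsc and "age_years" in meta.columns:
            no_age = out["subject_id"].map(meta["age_years"]).isna()
            out.loc[no_age, "msfsc_h"] = np.nan

    out["chronotype"] = classify_chronotype(out["msfsc_h"].to_numpy(), cutoffs)
    out["nap_group"] = classify_nap_group(out["mean_nap_min"].to_numpy())
    logger.info("summaries: %d subjects, %d with SJL, %d with MSFsc",
                len(out), int(out["sjl_h"].notna().sum()),
                int(out["msfsc_h"].notna().sum()))
    return out


def aggregate_subject(records: pd.DataFrame, **kwargs) -> pd.Series:
    """Summary row for a single subject's records."""
    if records["subject_id"].nunique() != 1:
        raise ValueError("aggregate_subject expects records of one subject")
    table = build_summaries(records, **kwargs)
    return table.iloc[0]


def write_summary_csv(summaries: pd.DataFrame, path) -> None:
    """Serialize the canonical summary columns (hours to 4 decimals)."""
    out = summaries[SUMMARY_CSV_COLUMNS].copy()
    for col in ["msw", "msf", "sdw", "sdf", "sjl_h", "msfsc_h"]:
        out[col] = out[col].round(4)
    for col in ["mean_nap_min", "total_sleep_work_min", "total_sleep_free_min"]:
        out[col] = out[col].round(2)
    out.to_csv(path, index=False)
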