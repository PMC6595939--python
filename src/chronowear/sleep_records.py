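"""Reading, validation and filtering of longitudinal wearable sleep records.

Time convention — the night axis
--------------------------------
Every nocturnal timestamp is mapped onto a *noon-anchored night axis*:
decimal hours elapsed since 12:00 noon of the ``anchor_date`` (the calendar
date of the evening on which the night begins).  A sleep onset at 00:15 of
the next day sits at 12.25 on this axis; a wake at 07:00 sits at 19.0.  Any
physiologically plausible nocturnal episode then lies inside a single
(0, 24) window with ``onset_axis < wake_axis``, which removes the midnight
wrap-around from all downstream arithmetic.  ``axis_to_clock`` converts
back to clock hours after midnight.

Calendar convention
-------------------
A *free night* is a night beginning on Friday or Saturday; every other
night (Sunday through Thursday evening) is a *work night*.  Weeks are
anchored on Sunday nights so that a complete 7-night week contains exactly
five work and two free nights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("chronowear")

#: anchor-date weekdays (Monday=0) whose nights are free nights
FREE_WEEKDAYS = (4, 5)  # Friday, Saturday

RECORD_COLUMNS = ["subject_id", "anchor_date", "onset", "wake",
                  "waso_min", "nap_min", "steps"]
SUBJECT_COLUMNS = ["subject_id", "age_years", "sex", "bmi"]
SEXES = ("male", "female", "unknown")


class DuplicateRecordError(ValueError):
    """More than one record for the same (subject, anchor_date) night."""


# ---------------------------------------------------------------------------
# time conversions
# ---------------------------------------------------------------------------

def clock_to_axis(clock_h):
    """Clock hours after midnight -> hours after noon of the anchor date."""
    return (np.asarray(clock_h, dtype=float) - 12.0) % 24.0


def axis_to_clock(axis_h):
    """Hours after noon of the anchor date -> clock hours after midnight."""
    return (np.asarray(axis_h, dtype=float) + 12.0) % 24.0


def parse_clock(text: str) -> float:
    """Parse ``HH:MM`` (optionally ``HH:MM:SS``) into decimal clock hours."""
    parts = str(text).strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"malformed time string {text!r}")
    try:
        h, m = int(parts[0]), int(parts[1])
        s = int(parts[2]) if len(parts) == 3 else 0
    except ValueError as exc:
        raise ValueError(f"malformed time string {text!r}") from exc
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"time out of range {text!r}")
    return h + m / 60.0 + s / 3600.0


def format_clock(clock_h: float) -> str:
    """Decimal clock hours -> ``HH:MM`` (rounded to the nearest minute)."""
    total = int(round(float(clock_h) * 60.0)) % (24 * 60)
    return f"{total // 60:02d}:{total % 60:02d}"


# ---------------------------------------------------------------------------
# calendar
# ---------------------------------------------------------------------------

def classify_night(anchor_date) -> str:
    """Return ``"free"`` for Friday/Saturday nights, else ``"work"``."""
    return "free" if pd.Timestamp(anchor_date).weekday() in FREE_WEEKDAYS else "work"


def is_free_night(anchor_dates: pd.Series) -> pd.Series:
    """Vectorised free-night flag for a datetime series."""
    return anchor_dates.dt.weekday.isin(FREE_WEEKDAYS)


def week_start(anchor_dates: pd.Series) -> pd.Series:
    """Sunday that opens the week each anchor date belongs to."""
    offset = (anchor_dates.dt.weekday + 1) % 7  # Sunday -> 0, Saturday -> 6
    return anchor_dates - pd.to_timedelta(offset, unit="D")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

@dataclass
class RowError:
    """One rejected CSV row: source file, 1-based line number, reason."""
    source: str
    line: int
    message: str


@dataclass
class ParsedData:
    records: pd.DataFrame
    subjects: pd.DataFrame
    errors: list = field(default_factory=list)


def _parse_clock_series(raw: pd.Series) -> pd.Series:
    parts = raw.astype(str).str.strip().str.extract(
        r"^(\d{1,2}):(\d{2})(?::(\d{2}))?$")
    h = pd.to_numeric(parts[0], errors="coerce")
    m = pd.to_numeric(parts[1], errors="coerce")
    s = pd.to_numeric(parts[2], errors="coerce").fillna(0.0)
    val = h + m / 60.0 + s / 3600.0
    val[(h >= 24) | (m >= 60) | (s >= 60)] = np.nan
    return val


def read_records(records_path, subjects_path=None) -> ParsedData:
    """Read the records (and optionally subjects) CSV into canonical frames.

    Malformed rows are rejected with a line-numbered :class:`RowError`;
    duplicate (subject_id, anchor_date) pairs raise
    :class:`DuplicateRecordError` naming the offending lines.

    The returned records frame has columns ``subject_id``, ``anchor_date``
    (datetime64), ``onset_axis``/``wake_axis`` (night-axis hours),
    ``waso_min``, ``nap_min``, ``steps`` (float, NaN = missing).
    """
    records_path = Path(records_path)
    raw = pd.read_csv(records_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in RECORD_COLUMNS[:-1] if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{records_path}: missing columns {missing_cols}")
    if "steps" not in raw.columns:
        raw["steps"] = ""

    lines = raw.index.to_numpy() + 2  # header is line 1
    anchor = pd.to_datetime(raw["anchor_date"].str.strip(), errors="coerce",
                            format="%Y-%m-%d")
    onset_axis = clock_to_axis(_parse_clock_series(raw["onset"]))
    wake_axis = clock_to_axis(_parse_clock_series(raw["wake"]))
    waso = pd.to_numeric(raw["waso_min"].str.strip(), errors="coerce")
    nap = pd.to_numeric(raw["nap_min"].str.strip(), errors="coerce")
    steps_txt = raw["steps"].str.strip()
    steps = pd.to_numeric(steps_txt, errors="coerce")

    tib_min = (wake_axis - onset_axis) * 60.0
    checks = [
        (anchor.isna(), "malformed anchor_date"),
        (np.isnan(onset_axis), "malformed onset time"),
        (np.isnan(wake_axis), "malformed wake time"),
        (~np.isnan(onset_axis) & ~np.isnan(wake_axis)
         & (wake_axis <= onset_axis), "wake <= onset on the night axis"),
        ((onset_axis <= 0) | (wake_axis >= 24), "episode outside night window"),
        (waso.isna() | (waso < 0), "invalid waso_min"),
        (waso.notna() & (waso >= tib_min), "waso_min >= time in bed"),
        (nap.isna() | (nap < 0) | (nap > 720), "nap_min outside [0, 720]"),
        ((steps_txt != "") & (steps.isna() | (steps < 0)), "invalid steps"),
    ]
    bad = np.zeros(len(raw), dtype=bool)
    errors: list[RowError] = []
    for mask, msg in checks:
        mask = np.asarray(mask, dtype=bool) & ~bad
        for ln in lines[mask]:
            errors.append(RowError(records_path.name, int(ln), msg))
        bad |= np.asarray(mask, dtype=bool)

    records = pd.DataFrame({
        "subject_id": raw["subject_id"].str.strip(),
        "anchor_date": anchor,
        "onset_axis": onset_axis,
        "wake_axis": wake_axis,
        "waso_min": waso.astype(float),
        "nap_min": nap.astype(float),
        "steps": steps.astype(float),
        "_line": lines,
    })[~bad].reset_index(drop=True)

    dup = records.duplicated(["subject_id", "anchor_date"], keep=False)
    if dup.any():
        rows = records.loc[dup, ["subject_id", "anchor_date", "_line"]]
        pairs = rows.groupby(["subject_id", "anchor_date"])["_line"].apply(list)
        detail = "; ".join(
            f"{sid} {date.date()}: lines {sorted(ls)}"
            for (sid, date), ls in pairs.items())
        raise DuplicateRecordError(
            f"duplicate (subject_id, anchor_date) records — {detail}")
    records = records.drop(columns="_line")

    if subjects_path is not None:
        subjects = read_subjects(subjects_path)
    else:
        subjects = pd.DataFrame({
            "subject_id": records["subject_id"].unique()})
        subjects["age_years"] = np.nan
        subjects["sex"] = "unknown"
        subjects["bmi"] = np.nan

    if errors:
        logger.warning("rejected %d malformed record rows", len(errors))
    return ParsedData(records=records, subjects=subjects, errors=errors)


def read_subjects(subjects_path) -> pd.DataFrame:
    subjects_path = Path(subjects_path)
    raw = pd.read_csv(subjects_path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SUBJECT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"{subjects_path}: missing columns {missing_cols}")
    sex = raw["sex"].str.strip().str.lower()
    sex = sex.where(sex.isin(SEXES), "unknown")
    out = pd.DataFrame({
        "subject_id": raw["subject_id"].str.strip(),
        "age_years": pd.to_numeric(raw["age_years"].str.strip(),
                                   errors="coerce"),
        "sex": sex,
        "bmi": pd.to_numeric(raw["bmi"].str.strip(), errors="coerce"),
    })
    if out["subject_id"].duplicated().any():
        dups = out.loc[out["subject_id"].duplicated(), "subject_id"].tolist()
        raise DuplicateRecordError(f"duplicate subject ids {dups}")
    return out


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

@dataclass
class ExclusionRules:
    """Cohort exclusion thresholds.

    Mean nocturnal sleep (time in bed minus WASO) outside
    ``[min_sleep_h, max_sleep_h]`` excludes a subject; ``per_night=True``
    switches the sleep filter to dropping individual out-of-range nights
    instead.  Age/BMI bounds are inclusive and only applied when the field
    is present.  Subjects need at least ``min_consecutive_nights``
    consecutive recorded nights.
    """
    min_sleep_h: float = 3.0
    max_sleep_h: float = 13.0
    min_age: float = 10.0
    max_age: float = 90.0
    min_bmi: float = 10.0
    max_bmi: float = 50.0
    min_consecutive_nights: int = 7
    per_night: bool = False


@dataclass
class FilterResult:
    records: pd.DataFrame
    subjects: pd.DataFrame
    ledger: pd.DataFrame  # rule, n_subjects_removed


def nocturnal_sleep_min(records: pd.DataFrame) -> pd.Series:
    """Per-night nocturnal sleep duration: time in bed minus WASO, minutes."""
    return (records["wake_axis"] - records["onset_axis"]) * 60.0 \
        - records["waso_min"]


def _longest_consecutive_run(dates: np.ndarray) -> int:
    days = np.unique(dates.astype("datetime64[D]").astype(np.int64))
    if days.size == 0:
        return 0
    breaks = np.flatnonzero(np.diff(days) != 1)
    lengths = np.diff(np.concatenate(([-1], breaks, [days.size - 1])))
    return int(lengths.max())


def apply_exclusions(records: pd.DataFrame, subjects: pd.DataFrame,
                     rules: ExclusionRules | None = None) -> FilterResult:
    """Apply the cohort exclusion rules; returns filtered data plus a ledger.

    The ledger counts subjects removed per rule (a subject failing several
    rules is counted once per rule) and has a final ``any`` row giving the
    size of the union, so input minus output equals the ``any`` count.
    Idempotent: a second application removes nothing.
    """
    rules = rules or ExclusionRules()
    rec = records.copy()

    if rules.per_night:
        dur_h = nocturnal_sleep_min(rec) / 60.0
        rec = rec[(dur_h >= rules.min_sleep_h)
                  & (dur_h <= rules.max_sleep_h)].reset_index(drop=True)

    ids = pd.Index(subjects["subject_id"]).union(rec["subject_id"].unique())
    meta = subjects.set_index("subject_id").reindex(ids)

    mean_sleep_h = (nocturnal_sleep_min(rec)
                    .groupby(rec["subject_id"]).mean() / 60.0).reindex(ids)
    run = (rec.groupby("subject_id")["anchor_date"]
           .apply(lambda s: _longest_consecutive_run(s.to_numpy()))
           .reindex(ids).fillna(0))

    removed: dict[str, pd.Index] = {}
    if not rules.per_night:
        removed["sleep<3h"] = ids[mean_sleep_h < rules.min_sleep_h]
        removed["sleep>13h"] = ids[mean_sleep_h > rules.max_sleep_h]
    removed["age<10"] = ids[meta["age_years"] < rules.min_age]
    removed["age>90"] = ids[meta["age_years"] > rules.max_age]
    removed["bmi<10"] = ids[meta["bmi"] < rules.min_bmi]
    removed["bmi>50"] = ids[meta["bmi"] > rules.max_bmi]
    removed["nights<7"] = ids[run < rules.min_consecutive_nights]

    drop = pd.Index([])
    ledger_rows = []
    for rule, idx in removed.items():
        ledger_rows.append({"rule": rule, "n_subjects_removed": len(idx)})
        drop = drop.union(idx)
    ledger_rows.append({"rule": "any", "n_subjects_removed": len(drop)})
    ledger = pd.DataFrame(ledger_rows)

    keep = ids.difference(drop)
    out_rec = rec[rec["subject_id"].isin(keep)].reset_index(drop=True)
    out_sub = (meta.loc[meta.index.isin(keep)].reset_index()
               .rename(columns={"index": "subject_id"}))
    out_sub["sex"] = out_sub["sex"].fillna("unknown")
    logger.info("exclusions: %d of %d subjects removed", len(drop), len(ids))
    return FilterResult(records=out_rec, subjects=out_sub, ledger=ledger)


# ---------------------------------------------------------------------------
# complete weeks
# ---------------------------------------------------------------------------

def complete_weeks(records: pd.DataFrame) -> pd.DataFrame:
    """Restrict to nights belonging to complete Sunday-anchored weeks.

    A complete week has all 7 consecutive nights recorded (5 work + 2 free).
    Returns the qualifying subset with an added ``week_start`` column.
    """
    rec = records.copy()
    rec["week_start"] = week_start(rec["anchor_date"])
    nights = rec.groupby(["subject_id", "week_start"])["anchor_date"].nunique()
    full = nights[nights == 7].index
    mask = pd.MultiIndex.from_frame(rec[["subject_id", "week_start"]]).isin(full)
    return rec[mask].reset_index(drop=True)


def subject_week_blocks(records: pd.DataFrame) -> list[pd.DataFrame]:
    """Complete 7-night blocks for a single subject's records."""
    if records["subject_id"].nunique() > 1:
        raise ValueError("subject_week_blocks expects one subject")
    cw = complete_weeks(records)
    return [g.sort_values("anchor_date").reset_index(drop=True)
            for _, g in cw.groupby("week_start")]


def write_exclusion_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, index=False)
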