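"""Synthetic wearable-style sleep cohorts with known ground truth.

The generator emulates the population structure of a large East-Asian
wearable cohort: work-night sleep onset around 00:15 (SD ≈ 70 min) and
wake around 7:00 (SD ≈ 66 min); free nights shifted ~13/22 minutes later
with additional between-subject spread; ~94 % of subjects napping, most
naps under an hour, and a weak negative coupling between nap and
nocturnal sleep duration (r ≈ −0.22); a near-normal chronotype
distribution whose age trajectory is biphasic, peaking at 4:00 at age 22
and declining into old age.

Model sketch (per subject i, all times on the noon-anchored night axis):

* latent chronotype  c_i = μ(age_i) + N(0, σ_c), with μ a piecewise-linear
  hinge rising to its peak at the configured age then declining linearly;
* work schedule      onset_i = base_onset + (c_i − E[μ]) + N(0, σ_on),
                     wake_i  = base_wake  + (c_i − E[μ]) + N(0, σ_wk),
  where the residual SDs are chosen so the *total* between-subject SDs
  match the configured onset/wake SDs and E[μ] (computed numerically from
  the age distribution) centres the cohort on the configured base times;
* free schedule      work schedule + subject-level shifts
                     N(Δ_onset, σ_Δon), N(Δ_wake, σ_Δwk);
* nights             subject schedule + N(0, σ_night) per night, rounded
  to whole minutes (the CSV dialect's resolution);
* naps               zero-inflated: napper w.p. p_nap, subject mean
  nap ~ Gamma(k, θ) (mode k>1 ⇒ (k−1)θ, default 17.5 min), nightly nap
  = subject mean + N(0, σ_nap_day), clipped to [0, 720] and rounded;
* WASO               base + κ·nap + N(0, σ_waso), clipped and rounded —
  the κ coupling is what induces the negative nap–nocturnal correlation;
* ground truth       MSW/MSF/SDw/SDf/SJL/MSFsc evaluated analytically on
  the minute-quantized subject-level schedule, so a noiseless
  configuration reproduces the latent values exactly through the pipeline.

All draws descend from one root seed through named
``numpy.random.SeedSequence`` spawns (subjects, schedule, nights, naps,
steps, missingness), so identical (config, seed) pairs give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .chronometrics import sleep_debt_corrected
from .sleep_records import (FREE_WEEKDAYS, axis_to_clock, clock_to_axis,
                            format_clock)

logger = logging.getLogger("chronowear")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generator parameters; defaults encode the emulated cohort structure."""

    n_subjects: int = 2000
    n_weeks: int = 2
    seed: int = 0
    start_date: str = "2017-04-02"  # a Sunday

    # population
    age_mix_weight_core: float = 0.8   # trunc-normal bulk vs uniform tail
    age_core_mean: float = 32.0
    age_core_sd: float = 9.0
    age_min: float = 10.0
    age_max: float = 90.0
    p_male: float = 0.64
    p_female: float = 0.14             # remainder is "unknown"
    bmi_mean: float = 23.5
    bmi_sd: float = 3.2
    bmi_min: float = 12.0
    bmi_max: float = 48.0
    age_missing_frac: float = 0.10
    bmi_missing_frac: float = 0.18
    steps_missing_frac: float = 0.05

    # chronotype trajectory μ(age): hinge through three anchor points
    chrono_young_age: float = 10.0
    chrono_young_h: float = 3.2
    chrono_peak_age: float = 22.0
    chrono_peak_h: float = 4.0
    chrono_old_age: float = 80.0
    chrono_old_h: float = 2.8
    chrono_sd_h: float = 1.0           # between-subject SD of latent chronotype

    # schedule (clock hours; SDs in minutes are total between-subject SDs)
    work_onset_clock_h: float = 0.25   # 00:15
    work_wake_clock_h: float = 7.0
    work_onset_sd_min: float = 70.5
    work_wake_sd_min: float = 66.3
    free_onset_shift_min: float = 13.0
    free_wake_shift_min: float = 22.0
    free_onset_shift_sd_min: float = 41.9   # sqrt(82^2 - 70.5^2)
    free_wake_shift_sd_min: float = 47.0    # sqrt(81.3^2 - 66.3^2)
    night_noise_sd_min: float = 30.0

    # WASO and naps
    waso_base_min: float = 5.0
    waso_sd_min: float = 10.0
    nap_coupling: float = 0.48         # minutes of extra WASO per nap minute
                                       # (calibrated so corr(nap, nocturnal)
                                       # ≈ -0.22 at the default noise levels)
    napper_frac: float = 0.94
    nap_gamma_shape: float = 2.0
    nap_gamma_scale_min: float = 17.5  # mode 17.5 min, mean 35 min
    nap_day_sd_min: float = 15.0

    # steps
    steps_log_mean: float = math.log(7500.0)
    steps_log_sd: float = 0.4
    steps_day_sd: float = 1200.0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_weeks <= 0:
            raise ValueError("n_subjects and n_weeks must be positive")
        probs = [self.p_male, self.p_female, self.napper_frac,
                 self.age_mix_weight_core, self.age_missing_frac,
                 self.bmi_missing_frac, self.steps_missing_frac]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_male + self.p_female > 1.0:
            raise ValueError("p_male + p_female must not exceed 1")
        sds = [self.chrono_sd_h, self.work_onset_sd_min, self.work_wake_sd_min,
               self.free_onset_shift_sd_min, self.free_wake_shift_sd_min,
               self.night_noise_sd_min, self.waso_sd_min, self.nap_day_sd_min,
               self.steps_day_sd]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be non-negative")
        if not (self.chrono_young_age < self.chrono_peak_age
                < self.chrono_old_age):
            raise ValueError("chronotype trajectory ages must be increasing")
        if pd.Timestamp(self.start_date).weekday() != 6:
            raise ValueError("start_date must be a Sunday")

    def noiseless(self) -> "SimConfig":
        """Copy with every within- and free-day noise source switched off.

        Work/free schedules coincide and every night repeats the subject's
        deterministic schedule, so the pipeline must recover SJL = 0 and
        MSFsc equal to the latent chronotype exactly.
        """
        return dataclasses.replace(
            self, night_noise_sd_min=0.0,
            free_onset_shift_min=0.0, free_wake_shift_min=0.0,
            free_onset_shift_sd_min=0.0, free_wake_shift_sd_min=0.0,
            waso_sd_min=0.0, nap_day_sd_min=0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# chronotype age trajectory
# ---------------------------------------------------------------------------

def mu_age(age, config: SimConfig | None = None):
    """Population mean chronotype μ(age): biphasic piecewise-linear hinge."""
    cfg = config or SimConfig()
    a = np.asarray(age, dtype=float)
    rise = cfg.chrono_young_h + (cfg.chrono_peak_h - cfg.chrono_young_h) * (
        (a - cfg.chrono_young_age)
        / (cfg.chrono_peak_age - cfg.chrono_young_age))
    fall = cfg.chrono_peak_h + (cfg.chrono_old_h - cfg.chrono_peak_h) * (
        (a - cfg.chrono_peak_age)
        / (cfg.chrono_old_age - cfg.chrono_peak_age))
    out = np.where(a <= cfg.chrono_peak_age, rise, fall)
    return float(out) if out.ndim == 0 else out


def expected_mu(config: SimConfig) -> float:
    """E[μ(age)] under the configured age mixture (numeric quadrature)."""
    cfg = config
    grid = np.linspace(cfg.age_min, cfg.age_max, 4001)
    a = (cfg.age_min - cfg.age_core_mean) / cfg.age_core_sd
    b = (cfg.age_max - cfg.age_core_mean) / cfg.age_core_sd
    core = scipy.stats.truncnorm.pdf(grid, a, b, loc=cfg.age_core_mean,
                                     scale=cfg.age_core_sd)
    unif = np.full_like(grid, 1.0 / (cfg.age_max - cfg.age_min))
    dens = cfg.age_mix_weight_core * core + (1 - cfg.age_mix_weight_core) * unif
    dens /= np.trapezoid(dens, grid)
    return float(np.trapezoid(mu_age(grid, cfg) * dens, grid))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    records: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def _quantize_h(x):
    """Round night-axis hours to the whole-minute grid of the CSV dialect."""
    return np.round(np.asarray(x, dtype=float) * 60.0) / 60.0


def simulate(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Generate a cohort; ``seed`` overrides ``config.seed`` when given."""
    cfg = config or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    cfg.validate()

    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    r_subj, r_sched, r_night, r_nap, r_steps, r_miss = (
        np.random.default_rng(s) for s in streams)
    n = cfg.n_subjects
    ids = np.array([f"S{i:06d}" for i in range(n)])

    # --- subjects -----------------------------------------------------------
    a = (cfg.age_min - cfg.age_core_mean) / cfg.age_core_sd
    b = (cfg.age_max - cfg.age_core_mean) / cfg.age_core_sd
    core = r_subj.random(n) < cfg.age_mix_weight_core
    age_core = scipy.stats.truncnorm.rvs(
        a, b, loc=cfg.age_core_mean, scale=cfg.age_core_sd, size=n,
        random_state=r_subj)
    age_unif = r_subj.uniform(cfg.age_min, cfg.age_max, n)
    ages = np.round(np.where(core, age_core, age_unif)).clip(
        cfg.age_min, cfg.age_max)
    sex = r_subj.choice(np.array(["male", "female", "unknown"]), size=n,
                        p=[cfg.p_male, cfg.p_female,
                           1.0 - cfg.p_male - cfg.p_female])
    bmi = np.round(np.clip(r_subj.normal(cfg.bmi_mean, cfg.bmi_sd, n),
                           cfg.bmi_min, cfg.bmi_max), 1)

    # --- latent chronotype and subject schedules ----------------------------
    chrono = mu_age(ages, cfg) + r_subj.normal(0.0, cfg.chrono_sd_h, n)
    offset = chrono - expected_mu(cfg)   # centred chronotype shift, hours
    resid_on = math.sqrt(max(cfg.work_onset_sd_min**2
                             - (60.0 * cfg.chrono_sd_h)**2, 0.0)) / 60.0
    resid_wk = math.sqrt(max(cfg.work_wake_sd_min**2
                             - (60.0 * cfg.chrono_sd_h)**2, 0.0)) / 60.0
    onset_w = clock_to_axis(cfg.work_onset_clock_h) + offset \
        + r_sched.normal(0.0, resid_on, n)
    wake_w = clock_to_axis(cfg.work_wake_clock_h) + offset \
        + r_sched.normal(0.0, resid_wk, n)
    wake_w = np.maximum(wake_w, onset_w + 3.0)  # keep schedules physical
    d_on = r_sched.normal(cfg.free_onset_shift_min,
                          cfg.free_onset_shift_sd_min, n) / 60.0
    d_wk = r_sched.normal(cfg.free_wake_shift_min,
                          cfg.free_wake_shift_sd_min, n) / 60.0
    onset_f = onset_w + d_on
    wake_f = wake_w + d_wk
    onset_w, wake_w, onset_f, wake_f = map(_quantize_h,
                                           (onset_w, wake_w, onset_f, wake_f))

    # --- naps and steps (subject level) -------------------------------------
    napper = r_nap.random(n) < cfg.napper_frac
    nap_mean = np.where(
        napper,
        r_nap.gamma(cfg.nap_gamma_shape, cfg.nap_gamma_scale_min, n), 0.0)
    nap_mean_q = np.round(np.clip(nap_mean, 0.0, 720.0))
    steps_mean = r_steps.lognormal(cfg.steps_log_mean, cfg.steps_log_sd, n)

    # --- nights -------------------------------------------------------------
    n_nights = 7 * cfg.n_weeks
    dates = pd.date_range(cfg.start_date, periods=n_nights, freq="D")
    free = np.isin(dates.weekday, FREE_WEEKDAYS)

    base_onset = np.where(free[None, :], onset_f[:, None], onset_w[:, None])
    base_wake = np.where(free[None, :], wake_f[:, None], wake_w[:, None])
    shape = (n, n_nights)
    night_sd_h = cfg.night_noise_sd_min / 60.0
    onset = _quantize_h(base_onset + r_night.normal(0.0, night_sd_h, shape))
    wake = _quantize_h(base_wake + r_night.normal(0.0, night_sd_h, shape))
    # keep extreme noise draws inside the open (0, 24) night-axis window
    onset = np.clip(onset, 1.0 / 60.0, None)
    wake = np.clip(wake, onset + 1.0 / 60.0, 24.0 - 1.0 / 60.0)

    nap_night = np.where(
        napper[:, None],
        np.round(np.clip(nap_mean_q[:, None]
                         + r_nap.normal(0.0, cfg.nap_day_sd_min, shape),
                         0.0, 720.0)),
        0.0)
    tib_min = (wake - onset) * 60.0
    waso = np.round(np.clip(
        cfg.waso_base_min + cfg.nap_coupling * nap_night
        + r_night.normal(0.0, cfg.waso_sd_min, shape),
        0.0, tib_min - 1.0))
    steps = np.round(np.clip(
        steps_mean[:, None] + r_steps.normal(0.0, cfg.steps_day_sd, shape),
        0.0, None))

    # --- missingness --------------------------------------------------------
    age_missing = r_miss.random(n) < cfg.age_missing_frac
    bmi_missing = r_miss.random(n) < cfg.bmi_missing_frac
    steps_missing = r_miss.random(n) < cfg.steps_missing_frac

    # --- ground truth (from the quantized deterministic schedule) -----------
    waso_true = np.round(np.clip(
        cfg.waso_base_min + cfg.nap_coupling * nap_mean_q, 0.0, None))
    msw_true = (onset_w + wake_w) / 2.0 - 12.0
    msf_true = (onset_f + wake_f) / 2.0 - 12.0
    sdw_true = (wake_w - onset_w) - waso_true / 60.0
    sdf_true = (wake_f - onset_f) - waso_true / 60.0
    msfsc_true = sleep_debt_corrected(msf_true, sdw_true, sdf_true) % 24.0
    sjl_true = msf_true - msw_true

    subjects = pd.DataFrame({
        "subject_id": ids,
        "age_years": np.where(age_missing, np.nan, ages),
        "sex": sex,
        "bmi": np.where(bmi_missing, np.nan, bmi)})
    truth = pd.DataFrame({
        "subject_id": ids,
        "true_msfsc_h": msfsc_true,
        "true_sjl_h": sjl_true,
        "napper": napper.astype(int)})
    records = pd.DataFrame({
        "subject_id": np.repeat(ids, n_nights),
        "anchor_date": np.tile(dates.to_numpy(), n),
        "onset_axis": onset.ravel(),
        "wake_axis": wake.ravel(),
        "waso_min": waso.ravel(),
        "nap_min": nap_night.ravel(),
        "steps": np.where(np.repeat(steps_missing, n_nights),
                          np.nan, steps.ravel()),
    })
    logger.info("simulated %d subjects x %d nights (seed %d)",
                n, n_nights, cfg.seed)
    return SimResult(records=records, subjects=subjects, truth=truth,
                     config=cfg)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(result: SimResult, outdir) -> dict:
    """Write records/subjects/truth CSVs plus a manifest; returns file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec = result.records
    onset_clock = axis_to_clock(rec["onset_axis"].to_numpy())
    wake_clock = axis_to_clock(rec["wake_axis"].to_numpy())
    out = pd.DataFrame({
        "subject_id": rec["subject_id"],
        "anchor_date": pd.to_datetime(rec["anchor_date"]).dt.strftime("%Y-%m-%d"),
        "onset": [format_clock(c) for c in onset_clock],
        "wake": [format_clock(c) for c in wake_clock],
        "waso_min": rec["waso_min"].astype(int),
        "nap_min": rec["nap_min"].astype(int),
        "steps": rec["steps"].map(
            lambda v: "" if pd.isna(v) else str(int(v))),
    })
    out.to_csv(outdir / "records.csv", index=False)

    sub = result.subjects.copy()
    sub["age_years"] = sub["age_years"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    sub["bmi"] = sub["bmi"].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
    sub.to_csv(outdir / "subjects.csv", index=False)

    truth = result.truth.copy()
    truth["true_msfsc_h"] = truth["true_msfsc_h"].round(6)
    truth["true_sjl_h"] = truth["true_sjl_h"].round(6)
    truth.to_csv(outdir / "truth.csv", index=False)

    manifest = {"config": result.config.to_dict(),
                "files": {"records": "records.csv",
                          "subjects": "subjects.csv",
                          "truth": "truth.csv"},
                "n_subjects": int(len(sub)),
                "n_records": int(len(out))}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest["files"]


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

def recover(truth: pd.DataFrame, summaries: pd.DataFrame) -> pd.DataFrame:
    """Compare pipeline estimates against generator ground truth.

    Returns one row per quantity (msfsc, sjl) with bias, RMSE and Spearman
    rank correlation over the subjects where both values exist.  Clock-hour
    quantities are compared on the circle (shortest signed difference), so
    a chronotype just before midnight is not scored as a ~24 h error.
    """
    merged = truth.merge(summaries, on="subject_id", how="inner")
    if len(merged) == 0:
        raise ValueError("no overlapping subject ids between truth and summaries")
    rows = []
    for name, true_col, est_col in [("msfsc", "true_msfsc_h", "msfsc_h"),
                                    ("sjl", "true_sjl_h", "sjl_h")]:
        sub = merged[[true_col, est_col]].dropna()
        if len(sub) < 3:
            continue
        if name == "msfsc":
            # clock hours: unwrap both onto the (-12, 12] window centred on
            # midnight, where all realistic chronotypes are contiguous
            t = ((sub[true_col] + 12.0) % 24.0) - 12.0
            e = ((sub[est_col] + 12.0) % 24.0) - 12.0
        else:
            t, e = sub[true_col], sub[est_col]
        err = e - t
        if np.ptp(t) == 0 or np.ptp(e) == 0:  # e.g. noiseless SJL ≡ 0
            rho = float("nan")
        else:
            rho = scipy.stats.spearmanr(t, e).statistic
        rows.append({"quantity": name, "n": int(len(sub)),
                     "bias": float(err.mean()),
                     "rmse": float(np.sqrt((err ** 2).mean())),
                     "rank_corr": float(rho)})
    return pd.DataFrame(rows)
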