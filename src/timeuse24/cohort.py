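"""Synthetic cohort generator for the 24-h time-use pipeline.

Emulates a two-week wrist-accelerometer feasibility study in adults with
a diabetes-related foot ulcer: ~29 mostly male participants in their
late sixties wear a monitor for 14 days, keep a sleep diary, and report
physical (PCS-12) and mental (MCS-12) quality-of-life component scores.
The generator emits

* a long epoch table (60-s magnitudes, 1440 epochs per participant-day),
* a daily diary table (self-reported sleep onset/wake, with misreport
  noise),
* a participant metadata table (demographics plus outcome scores drawn
  from a linear model on the ilr coordinates of the true composition),
* ground-truth tables (per-participant true compositions and
  per-day planted minutes) so every downstream stage can be verified
  by round-trip.

Epoch magnitudes are drawn uniformly *within* each intensity class's
cutpoint interval (sedentary 0-117, LPA 118-402, MPA 403-1130,
VPA >= 1131 g.min), so cutpoint classification is exactly invertible and
the pipeline's correctness is provable rather than approximate.  Planted
non-wear intervals are near-zero and flat; sleep windows are quiescent
except for scattered interior "restless" epochs that set the planted
sleep efficiency.

Defaults reproduce the study conditions: daily means of
484.6 / 747.1 / 172.4 / 17.5 min of sleep / sedentary / LPA / MVPA plus
18.4 min of non-wear (sums to 1440 exactly), age 68.4 (SD 9.2) years,
92% male, PCS-12 35.5 (SD 6.9), MCS-12 49.1 (SD 12.2).  A configurable
participant fraction has zero true MVPA (exercising zero replacement)
and another fraction never wears the monitor (exercising the retention
metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .coda import DAY_MINUTES, PARTS, close_composition, ilr_transform

EPOCHS_PER_DAY = 1440

#: default daily-minute means of the four behaviours (min/day)
DEFAULT_TARGET_MEANS = (484.6, 747.1, 172.4, 17.5)
#: default expected monitor non-wear (min/day)
DEFAULT_NONWEAR_RATE = 18.4


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_participants: int = 29
    n_days: int = 14
    epoch_seconds: int = 60            # fixed; the ingestion granularity
    target_means: tuple[float, float, float, float] = DEFAULT_TARGET_MEANS
    between_person_sd: tuple[float, float, float, float] = (55.0, 0.0, 45.0, 15.0)
    nonwear_rate: float = DEFAULT_NONWEAR_RATE
    day_sd: float = 20.0               # day-to-day wobble of each behaviour
    sleep_efficiency: float = 0.75     # planted quiescent fraction of SPT
    diary_error_sd: float = 10.0       # min; diary misreport noise
    weekend_sedentary_multiplier: float = 1.05
    zero_mvpa_fraction: float = 0.15   # participants with no MVPA at all
    dropout_fraction: float = 0.14     # participants who never wear the monitor
    age_mean: float = 68.4
    age_sd: float = 9.2
    male_fraction: float = 0.92
    start_date: str = "2023-01-02"     # a Monday
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.epoch_seconds != 60:
            raise ValueError("only 60-s epochs are supported")
        if any(t <= 0 for t in self.target_means):
            raise ValueError("target_means must all be positive")
        total = sum(self.target_means) + self.nonwear_rate
        if abs(total - DAY_MINUTES) > 1.0:
            raise ValueError(
                f"target_means + nonwear_rate must sum to {DAY_MINUTES:.0f} "
                f"within 1 min (got {total:.1f})")


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Linear outcome model on the leading-rotation ilr coordinates.

    outcome = intercept + z . ilr_betas + covariates . covariate_betas
              + Normal(0, noise_sd)

    where z are the rotation-0 (sleep-first) pivot ilr coordinates of the
    participant's true behaviour composition.  ``intercept=None`` means
    "calibrate so the expected outcome at the cohort's target composition
    equals ``target_mean``".
    """

    outcome_name: str = "pcs12"
    ilr_betas: tuple[float, float, float] = (0.0, 0.0, 0.0)
    covariate_betas: dict = field(default_factory=dict)  # name -> beta
    noise_sd: float = 6.9
    intercept: float | None = None
    target_mean: float = 35.5

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_outcome_specs() -> list[OutcomeModelSpec]:
    """PCS-12 and MCS-12 outcome models at the study's means and spreads.

    The planted ilr effects follow the observed direction of association:
    more sleep and MVPA relative to the rest is better, more sedentary
    time and LPA relative to the rest is worse.
    """
    return [
        OutcomeModelSpec("pcs12", ilr_betas=(6.0, -5.0, -1.5),
                         noise_sd=6.0, target_mean=35.5),
        OutcomeModelSpec("mcs12", ilr_betas=(7.0, -4.0, -4.0),
                         noise_sd=11.0, target_mean=49.1),
    ]


@dataclass
class ParticipantProfile:
    """Ground-truth state of one synthetic participant."""

    id: str
    age: float
    sex: str
    education: str
    diabetes_duration: float
    ulcer_severity: str
    true_parts: tuple[float, float, float, float]  # sleep/sed/lpa/mvpa min/day
    sleep_onset_min: int        # habitual onset, minutes past midnight
    diary_error_sd: float
    is_dropout: bool


class CohortTables(NamedTuple):
    epochs: pd.DataFrame
    diary: pd.DataFrame
    metadata: pd.DataFrame
    truth_participants: pd.DataFrame
    truth_days: pd.DataFrame


# ---------------------------------------------------------------------------
# participant-level generation

_EDUCATION_LEVELS = ("year12_or_below", "certificate_or_diploma", "bachelor_or_higher")
_EDUCATION_PROBS = (0.60, 0.24, 0.16)
_ULCER_LEVELS = ("low", "moderate", "high")


def generate_participants(spec: CohortSpec,
                          rng: np.random.Generator) -> list[ParticipantProfile]:
    """Draw per-participant true mean compositions and demographics.

    Sleep and LPA are drawn normally around their targets; MVPA is drawn
    lognormally (its empirical distribution is right-skewed, with a
    median well below the mean) among the non-zero-MVPA participants so
    that the cohort-wide expectation stays at the target; sedentary time
    absorbs the remainder so each participant's behaviours plus the
    expected non-wear fill 1440 min exactly.
    """
    n = spec.n_participants
    tm = np.asarray(spec.target_means, float)
    sd = np.asarray(spec.between_person_sd, float)

    n_zero = int(round(spec.zero_mvpa_fraction * n))
    n_drop = int(round(spec.dropout_fraction * n))
    idx = rng.permutation(n)
    zero_set = set(idx[:n_zero])
    drop_set = set(idx[n_zero:n_zero + n_drop]) if n_zero + n_drop <= n else set(idx[n_zero:])

    profiles = []
    for i in range(n):
        sleep = max(240.0, rng.normal(tm[0], sd[0]))
        lpa = max(20.0, rng.normal(tm[2], sd[2]))
        if i in zero_set:
            mvpa = 0.0
        elif spec.zero_mvpa_fraction < 1.0:
            # lognormal with mean target/(1 - zero fraction); sigma fixed at the
            # observed skew (median ~ 0.74 x mean)
            mean_nonzero = tm[3] / (1.0 - spec.zero_mvpa_fraction)
            sigma = 0.77 if sd[3] > 0 else 0.0
            mu = np.log(mean_nonzero) - sigma**2 / 2.0
            mvpa = float(rng.lognormal(mu, sigma)) if sigma > 0 else mean_nonzero
            mvpa = min(mvpa, 180.0)
        else:
            mvpa = 0.0
        sedentary = DAY_MINUTES - spec.nonwear_rate - sleep - lpa - mvpa
        if sedentary <= 60.0:
            # pathological draw; pull sleep/LPA back toward target
            sleep, lpa = tm[0], tm[2]
            sedentary = DAY_MINUTES - spec.nonwear_rate - sleep - lpa - mvpa
        profiles.append(ParticipantProfile(
            id=f"P{i + 1:03d}",
            age=float(np.round(np.clip(rng.normal(spec.age_mean, spec.age_sd), 35, 95), 1)),
            sex="male" if rng.random() < spec.male_fraction else "female",
            education=str(rng.choice(_EDUCATION_LEVELS, p=_EDUCATION_PROBS)),
            diabetes_duration=float(np.round(np.clip(rng.normal(20.0, 11.0), 0.5, 60), 1)),
            ulcer_severity=str(rng.choice(_ULCER_LEVELS)),
            true_parts=(float(sleep), float(sedentary), float(lpa), float(mvpa)),
            sleep_onset_min=int(23 * 60 + rng.integers(-45, 46)),
            diary_error_sd=spec.diary_error_sd,
            is_dropout=i in drop_set,
        ))
    return profiles


#: latent MVPA floor (min/day) used only to form the outcome-generating ilr
#: for participants whose planted epoch-level MVPA is exactly zero
MVPA_OUTCOME_FLOOR = 2.0


def generate_outcomes(profiles: list[ParticipantProfile],
                      outcome_specs: list[OutcomeModelSpec],
                      rng: np.random.Generator,
                      target_means=DEFAULT_TARGET_MEANS
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Outcome scores from the linear ilr model, plus the parameter record.

    Returns (metadata table, outcome-parameter ground truth).
    """
    comp = np.array([p.true_parts for p in profiles], float)
    comp[:, 3] = np.maximum(comp[:, 3], MVPA_OUTCOME_FLOOR)
    z = ilr_transform(close_composition(comp), rotation=0)
    z_ref = ilr_transform(close_composition(np.asarray(target_means, float)))

    meta = pd.DataFrame({
        "participant_id": [p.id for p in profiles],
        "age": [p.age for p in profiles],
        "sex": [p.sex for p in profiles],
        "education": [p.education for p in profiles],
        "diabetes_duration": [p.diabetes_duration for p in profiles],
        "ulcer_severity": [p.ulcer_severity for p in profiles],
    })
    param_rows = []
    for ospec in outcome_specs:
        betas = np.asarray(ospec.ilr_betas, float)
        if ospec.intercept is None:
            intercept = ospec.target_mean - float(z_ref @ betas)
        else:
            intercept = ospec.intercept
        y = intercept + z @ betas
        for name, b in ospec.covariate_betas.items():
            y = y + b * meta[name].to_numpy(float)
        y = y + rng.normal(0.0, ospec.noise_sd, size=len(profiles))
        meta[ospec.outcome_name] = np.round(y, 2)
        param_rows.append({
            "outcome_name": ospec.outcome_name,
            "intercept": intercept,
            "ilr_beta1": betas[0], "ilr_beta2": betas[1], "ilr_beta3": betas[2],
            "noise_sd": ospec.noise_sd,
        })
    return meta, pd.DataFrame(param_rows)


# ---------------------------------------------------------------------------
# day-level generation

def _split_waking_minutes(profile: ParticipantProfile, waking: int,
                          weekend: bool, spec: CohortSpec,
                          rng: np.random.Generator) -> tuple[int, int, int]:
    """Integer (sedentary, lpa, mvpa) minutes filling the waking budget."""
    sleep_t, sed_t, lpa_t, mvpa_t = profile.true_parts
    if weekend:
        sed_t *= spec.weekend_sedentary_multiplier
    props = np.array([sed_t, lpa_t, mvpa_t], float)
    props = props / props.sum()
    target = props * waking
    if spec.day_sd > 0:
        noise = rng.normal(0.0, spec.day_sd, size=2)
    else:
        noise = np.zeros(2)
    lpa = target[1] + noise[0]
    mvpa = (target[2] + noise[1] * 0.25) if mvpa_t > 0 else 0.0
    lpa = int(np.clip(round(lpa), 0, waking))
    mvpa = int(np.clip(round(mvpa), 0, max(waking - lpa, 0)))
    sed = waking - lpa - mvpa
    return sed, lpa, mvpa


def _draw_magnitudes(n: int, low: float, high: float,
                     rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(low, high, size=n)


def generate_epoch_day(profile: ParticipantProfile, day_type: str,
                       spec: CohortSpec, rng: np.random.Generator
                       ) -> tuple[np.ndarray, dict, dict]:
    """One midnight-to-midnight day of 1440 epoch magnitudes.

    Returns (magnitudes, diary record fields, ground-truth fields).
    The sleep window wraps around midnight; the day is stationary, so
    the within-day circular window matches the across-midnight night.
    """
    if profile.is_dropout:
        mags = rng.uniform(0.0, 2.0, size=EPOCHS_PER_DAY)
        onset = profile.sleep_onset_min
        spt = int(round(profile.true_parts[0]))
        truth = dict(sleep_min=0, sedentary_min=0, lpa_min=0, mvpa_min=0,
                     nonwear_min=EPOCHS_PER_DAY, onset_min=np.nan,
                     offset_min=np.nan, efficiency_pct=np.nan)
        diary = _diary_fields(onset, (onset + spt) % EPOCHS_PER_DAY,
                              profile.diary_error_sd, rng)
        return mags, diary, truth

    weekend = day_type == "weekend"
    # sleep period time for the day
    spt = int(round(profile.true_parts[0]
                    + (rng.normal(0.0, spec.day_sd) if spec.day_sd > 0 else 0.0)))
    spt = int(np.clip(spt, 240, 720))
    onset = profile.sleep_onset_min % EPOCHS_PER_DAY
    offset = (onset + spt) % EPOCHS_PER_DAY

    # non-wear block (waking hours only)
    waking = EPOCHS_PER_DAY - spt
    expected_block = 90.0
    p_block = min(spec.nonwear_rate / expected_block, 1.0) if spec.nonwear_rate > 0 else 0.0
    nonwear_len = int(rng.integers(60, 121)) if rng.random() < p_block else 0
    nonwear_len = min(nonwear_len, max(waking - 120, 0))

    sed, lpa, mvpa = _split_waking_minutes(
        profile, waking - nonwear_len, weekend, spec, rng)

    mags = np.empty(EPOCHS_PER_DAY)
    sleep_idx = (onset + np.arange(spt)) % EPOCHS_PER_DAY
    waking_idx = (offset + np.arange(waking)) % EPOCHS_PER_DAY

    # sleep window: quiescent, with restless epochs in the interior that set
    # the planted efficiency; the first/last stretch stays quiescent so onset
    # and offset are recoverable
    guard = 12
    n_restless = int(round((1.0 - spec.sleep_efficiency) * spt))
    n_restless = min(n_restless, max(spt - 2 * guard, 0))
    mags[sleep_idx] = _draw_magnitudes(spt, 5.0, 39.0, rng)
    if n_restless > 0:
        interior = sleep_idx[guard:spt - guard]
        restless = rng.choice(interior, size=n_restless, replace=False)
        mags[restless] = _draw_magnitudes(n_restless, 41.0, 117.0, rng)

    # waking layout: a guard band of upper-range sedentary epochs on both
    # sides of the sleep window (above the quiescence threshold, so onset
    # and offset detection cannot drift into waking time), then an optional
    # non-wear block, then shuffled intensity epochs
    guard_band = int(min(60, sed // 2, max(waking // 4, 0)))
    head, tail = waking_idx[:guard_band], waking_idx[waking - guard_band:]
    if guard_band:
        mags[head] = _draw_magnitudes(guard_band, 41.0, 117.0, rng)
        mags[tail] = _draw_magnitudes(guard_band, 41.0, 117.0, rng)
    interior = waking_idx[guard_band:waking - guard_band]
    if nonwear_len > 0:
        start = int(rng.integers(0, interior.size - nonwear_len + 1))
        nw_idx = interior[start:start + nonwear_len]
        mags[nw_idx] = _draw_magnitudes(nonwear_len, 0.0, 3.0, rng)
        active_idx = np.concatenate([interior[:start],
                                     interior[start + nonwear_len:]])
    else:
        active_idx = interior
    labels = np.concatenate([
        np.zeros(sed - 2 * guard_band, dtype=int), np.ones(lpa, dtype=int),
        np.full(mvpa, 2, dtype=int)])
    rng.shuffle(labels)
    sed_mask, lpa_mask, mvpa_mask = labels == 0, labels == 1, labels == 2
    vals = np.empty(active_idx.size)
    vals[sed_mask] = _draw_magnitudes(int(sed_mask.sum()), 0.0, 117.0, rng)
    vals[lpa_mask] = _draw_magnitudes(int(lpa_mask.sum()), 118.0, 402.0, rng)
    n_mvpa = int(mvpa_mask.sum())
    if n_mvpa:
        mv = _draw_magnitudes(n_mvpa, 403.0, 1130.0, rng)
        vig = rng.random(n_mvpa) < 0.10  # a tenth of MVPA epochs are vigorous
        mv[vig] = _draw_magnitudes(int(vig.sum()), 1131.0, 1800.0, rng)
        vals[mvpa_mask] = mv
    mags[active_idx] = vals

    eff = 100.0 * (spt - n_restless) / spt
    truth = dict(sleep_min=spt, sedentary_min=sed, lpa_min=lpa, mvpa_min=mvpa,
                 nonwear_min=nonwear_len, onset_min=onset, offset_min=offset,
                 efficiency_pct=eff)
    diary = _diary_fields(onset, offset, profile.diary_error_sd, rng)
    return mags, diary, truth


def _fmt_clock(minute: float) -> str:
    m = int(round(minute)) % EPOCHS_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


def _diary_fields(onset: int, offset: int, error_sd: float,
                  rng: np.random.Generator) -> dict:
    # misreport noise is truncated at 3 sd: diaries are imprecise, not wrong
    # by hours
    bound = 3.0 * error_sd
    e1 = np.clip(rng.normal(0.0, error_sd), -bound, bound) if error_sd > 0 else 0.0
    e2 = np.clip(rng.normal(0.0, error_sd), -bound, bound) if error_sd > 0 else 0.0
    return {
        "diary_sleep_onset": _fmt_clock(onset + e1),
        "diary_wake": _fmt_clock(offset + e2),
        "nonwear_note": "",
    }


# ---------------------------------------------------------------------------
# whole-cohort generation

def generate_cohort(spec: CohortSpec,
                    outcome_specs: list[OutcomeModelSpec] | None = None
                    ) -> CohortTables:
    """Generate the full synthetic study, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    if outcome_specs is None:
        outcome_specs = default_outcome_specs()
    profiles = generate_participants(spec, rng)
    metadata, outcome_params = generate_outcomes(
        profiles, outcome_specs, rng, spec.target_means)

    dates = pd.date_range(spec.start_date, periods=spec.n_days, freq="D")
    epoch_rows, diary_rows, truth_day_rows = [], [], []
    minutes = np.arange(EPOCHS_PER_DAY)
    for profile in profiles:
        for date in dates:
            dt = "weekend" if date.dayofweek >= 5 else "weekday"
            mags, diary, truth = generate_epoch_day(profile, dt, spec, rng)
            stamps = date + pd.to_timedelta(minutes, unit="m")
            epoch_rows.append(pd.DataFrame({
                "participant_id": profile.id,
                "timestamp": stamps.strftime("%Y-%m-%dT%H:%M:%S"),
                "magnitude_gmin": np.round(mags, 3),
            }))
            diary_rows.append({"participant_id": profile.id,
                               "date": date.strftime("%Y-%m-%d"), **diary})
            truth_day_rows.append({"participant_id": profile.id,
                                   "date": date.strftime("%Y-%m-%d"),
                                   "day_type": dt, **truth})
    epochs = pd.concat(epoch_rows, ignore_index=True)
    diary = pd.DataFrame(diary_rows)
    truth_days = pd.DataFrame(truth_day_rows)
    truth_participants = pd.DataFrame([{
        "participant_id": p.id,
        "true_sleep_min": p.true_parts[0],
        "true_sedentary_min": p.true_parts[1],
        "true_lpa_min": p.true_parts[2],
        "true_mvpa_min": p.true_parts[3],
        "sleep_onset_min": p.sleep_onset_min,
        "is_dropout": p.is_dropout,
    } for p in profiles])
    # outcome parameters travel in their own small table
    truth_participants.attrs["outcome_params"] = outcome_params
    return CohortTables(epochs, diary, metadata, truth_participants, truth_days)


def write_cohort(tables: CohortTables, outdir) -> dict:
    """Write the cohort tables as the package's CSV dialects."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [("epochs", tables.epochs), ("diary", tables.diary),
                     ("metadata", tables.metadata),
                     ("truth_participants", tables.truth_participants),
                     ("truth_days", tables.truth_days)]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    params = tables.truth_participants.attrs.get("outcome_params")
    if params is not None:
        path = outdir / "truth_outcome_params.csv"
        params.to_csv(path, index=False)
        paths["truth_outcome_params"] = str(path)
    return paths
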