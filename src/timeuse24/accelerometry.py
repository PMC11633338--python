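"""Epoch-level accelerometry processing for 24-h time-use estimation.

Turns 60-s epoch acceleration magnitudes from a wrist-worn monitor into
per-day time-use summaries and per-participant weighted 24-h
compositions.  The processing chain per monitored day is:

1. non-wear detection (long flat runs of near-zero magnitude),
2. sleep-period detection anchored on the self-report diary window,
3. intensity classification of the remaining waking worn epochs by
   magnitude cutpoints (sedentary < 118 <= LPA < 403 <= MPA < 1131 <= VPA,
   in gravity-units-per-minute; MVPA = MPA + VPA),
4. day-validity screening (>= 10 h waking wear and >= 200 min sleep),
5. participant inclusion (>= 4 valid days including a weekend day) and
   5:2 weekday:weekend weighting of the daily minutes.

Days run midnight to midnight (1440 epochs).  Because habitual sleep
straddles midnight, each day is treated as circular for sleep detection:
the night is assessed within the same 1440-epoch series by wrapping.

Sleep minutes are *sleep period time* (onset to offset), not
efficiency-adjusted sleep; restless epochs inside the period count as
sleep, and sleep efficiency (the percent of the period spent quiescent)
is carried separately.  Non-wear inside the sleep period also counts as
sleep; the non-wear total covers waking hours only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

EPOCHS_PER_DAY = 1440

#: intensity class labels in cutpoint order
INTENSITY_CLASSES = ("sedentary", "lpa", "mpa", "vpa")


@dataclass(frozen=True)
class AccelConfig:
    """Tunable parameters of the epoch-processing chain."""

    cutpoints: tuple[float, float, float] = (118.0, 403.0, 1131.0)
    nonwear_floor: float = 10.0        # g.min; all epochs in a run below this
    nonwear_max_range: float = 5.0     # g.min; max-min within the run
    nonwear_min_run: int = 60          # epochs (minutes)
    sleep_quiescence: float = 40.0     # g.min; epoch counts as quiescent
    sleep_min_run: int = 10            # consecutive quiescent epochs at onset
    sleep_search: int = 60             # minutes around the diary window
    sleep_fallback_min: int = 200      # min quiescent block without a diary
    min_wear_waking: int = 600         # valid day: >= 10 h waking wear
    min_sleep: int = 200               # valid day: >= 200 min sleep
    min_valid_days: int = 4
    min_weekend_days: int = 1
    weekday_weight: int = 5
    weekend_weight: int = 2


@dataclass
class SleepPeriod:
    """Detected sleep window on a circular 1440-epoch day."""

    onset: int          # epoch index of sleep onset
    offset: int         # epoch index of sleep offset (exclusive)
    duration_min: int   # sleep period time, (offset - onset) mod 1440
    efficiency_pct: float

    def mask(self) -> np.ndarray:
        m = np.zeros(EPOCHS_PER_DAY, dtype=bool)
        idx = (self.onset + np.arange(self.duration_min)) % EPOCHS_PER_DAY
        m[idx] = True
        return m


@dataclass
class DailySummary:
    """Minutes of each time-use domain for one participant-day."""

    participant_id: str
    date: str
    day_type: str       # "weekday" | "weekend"
    sleep_min: float
    sedentary_min: float
    lpa_min: float
    mvpa_min: float
    nonwear_min: float
    sleep_efficiency_pct: float
    wear_waking_min: float
    is_valid: bool

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParticipantTimeUse:
    """5:2 weekday:weekend weighted daily minutes for one participant."""

    participant_id: str
    sleep_min: float
    sedentary_min: float
    lpa_min: float
    mvpa_min: float
    nonwear_min: float
    n_valid_days: int
    n_valid_weekend_days: int
    mean_sleep_efficiency_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


def classify_epoch(magnitude, cutpoints=(118.0, 403.0, 1131.0)) -> np.ndarray:
    """Intensity class index (0=sedentary, 1=LPA, 2=MPA, 3=VPA).

    Cutpoints are inclusive on the left: a magnitude exactly at a
    cutpoint falls in the higher class, i.e. the class index equals the
    number of cutpoints <= magnitude.
    """
    m = np.asarray(magnitude, dtype=float)
    if np.any(m < 0):
        raise ValueError("epoch magnitudes must be non-negative")
    return np.searchsorted(np.asarray(cutpoints, float), m, side="right")


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start, length) pairs (linear, not circular)."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts, ends - starts))


def detect_non_wear(magnitudes, config: AccelConfig = AccelConfig(),
                    diary_nonwear: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of non-wear epochs.

    Flags maximal runs of at least ``nonwear_min_run`` consecutive epochs
    whose magnitudes all sit below ``nonwear_floor`` and whose range is
    below ``nonwear_max_range`` — the flat, near-zero signature of a
    monitor lying on a table.  An optional diary non-wear mask extends
    the algorithmic flags.
    """
    m = np.asarray(magnitudes, dtype=float)
    low = m < config.nonwear_floor
    out = np.zeros_like(low)
    for start, length in _runs(low):
        if length < config.nonwear_min_run:
            continue
        for seg_start, seg_len in _stable_segments(
                m[start:start + length], config.nonwear_max_range):
            if seg_len >= config.nonwear_min_run:
                out[start + seg_start:start + seg_start + seg_len] = True
    if diary_nonwear is not None:
        out |= np.asarray(diary_nonwear, dtype=bool)
    return out


def _stable_segments(values: np.ndarray, max_range: float):
    """Maximal segments whose max-min stays below ``max_range``.

    Greedy left-to-right split: a single epoch outside the tolerance
    splits the run rather than discarding it, so a genuine flat block
    flanked by borderline epochs is still recovered.
    """
    segments = []
    left = 0
    lo = hi = values[0]
    for i in range(1, values.size):
        lo2, hi2 = min(lo, values[i]), max(hi, values[i])
        if hi2 - lo2 >= max_range:
            segments.append((left, i - left))
            left = i
            lo = hi = values[i]
        else:
            lo, hi = lo2, hi2
    segments.append((left, values.size - left))
    return segments


def _quiescent_run_starts_at(q: np.ndarray, idx: int, run: int) -> bool:
    take = (idx + np.arange(run)) % EPOCHS_PER_DAY
    return bool(q[take].all())


def _quiescent_run_ends_at(q: np.ndarray, idx: int, run: int) -> bool:
    take = (idx - 1 - np.arange(run)) % EPOCHS_PER_DAY
    return bool(q[take].all())


def detect_sleep_period(magnitudes,
                        diary_onset_min: float | None = None,
                        diary_wake_min: float | None = None,
                        config: AccelConfig = AccelConfig()) -> SleepPeriod | None:
    """Locate the night's sleep period on a circular day.

    With a diary window, onset is the start of the first run of
    ``sleep_min_run`` consecutive quiescent epochs (magnitude below
    ``sleep_quiescence``) within ``sleep_search`` minutes of the diary
    sleep-onset time, and offset is found symmetrically from the diary
    wake time (latest epoch where a quiescent run ends).  Without a
    diary the fallback is the longest circular quiescent block, accepted
    only if it reaches ``sleep_fallback_min`` minutes.

    Returns ``None`` when no candidate window is found — the day is then
    sleep-undetectable and invalid.
    """
    m = np.asarray(magnitudes, dtype=float)
    if m.size != EPOCHS_PER_DAY:
        raise ValueError(f"expected {EPOCHS_PER_DAY} epochs, got {m.size}")
    q = m < config.sleep_quiescence

    if diary_onset_min is None or diary_wake_min is None:
        return _fallback_sleep(q, config)

    do = int(round(diary_onset_min)) % EPOCHS_PER_DAY
    dw = int(round(diary_wake_min)) % EPOCHS_PER_DAY
    onset = None
    for c in range(do - config.sleep_search, do + config.sleep_search + 1):
        if _quiescent_run_starts_at(q, c % EPOCHS_PER_DAY, config.sleep_min_run):
            onset = c % EPOCHS_PER_DAY
            break
    offset = None
    for c in range(dw + config.sleep_search, dw - config.sleep_search - 1, -1):
        if _quiescent_run_ends_at(q, c % EPOCHS_PER_DAY, config.sleep_min_run):
            offset = c % EPOCHS_PER_DAY
            break
    if onset is None or offset is None:
        return _fallback_sleep(q, config)
    duration = (offset - onset) % EPOCHS_PER_DAY
    if duration == 0:
        return None
    idx = (onset + np.arange(duration)) % EPOCHS_PER_DAY
    eff = 100.0 * q[idx].mean()
    return SleepPeriod(onset, offset, duration, float(eff))


def _fallback_sleep(q: np.ndarray, config: AccelConfig) -> SleepPeriod | None:
    """Longest circular quiescent block, if long enough to be a night."""
    qq = np.concatenate([q, q])
    best_start, best_len = -1, 0
    for start, length in _runs(qq):
        if start >= EPOCHS_PER_DAY:
            continue
        length = min(length, EPOCHS_PER_DAY)
        if length > best_len:
            best_start, best_len = start, length
    if best_len < config.sleep_fallback_min:
        return None
    onset = best_start % EPOCHS_PER_DAY
    offset = (onset + best_len) % EPOCHS_PER_DAY
    return SleepPeriod(onset, offset, best_len, 100.0)


def summarize_day(magnitudes, nonwear_mask, sleep: SleepPeriod | None,
                  participant_id: str, date, day_type: str,
                  config: AccelConfig = AccelConfig()) -> DailySummary:
    """Combine the detectors into a day's five-part time-use summary.

    Epochs inside the sleep period count as sleep regardless of wear;
    waking epochs flagged non-wear count as non-wear; the remaining
    waking worn epochs are classified by cutpoint.  The five totals sum
    to exactly 1440.
    """
    m = np.asarray(magnitudes, dtype=float)
    nw = np.asarray(nonwear_mask, dtype=bool)
    if sleep is not None:
        sleep_mask = sleep.mask()
        sleep_min = sleep.duration_min
        eff = sleep.efficiency_pct
    else:
        sleep_mask = np.zeros(EPOCHS_PER_DAY, dtype=bool)
        sleep_min = 0
        eff = float("nan")
    waking_nw = nw & ~sleep_mask
    worn_waking = ~sleep_mask & ~waking_nw
    classes = classify_epoch(m[worn_waking], config.cutpoints)
    sed = int(np.sum(classes == 0))
    lpa = int(np.sum(classes == 1))
    mvpa = int(np.sum(classes >= 2))
    nonwear_min = int(waking_nw.sum())
    wear_waking = EPOCHS_PER_DAY - sleep_min - nonwear_min
    summary = DailySummary(
        participant_id=str(participant_id),
        date=str(date),
        day_type=day_type,
        sleep_min=float(sleep_min),
        sedentary_min=float(sed),
        lpa_min=float(lpa),
        mvpa_min=float(mvpa),
        nonwear_min=float(nonwear_min),
        sleep_efficiency_pct=float(eff),
        wear_waking_min=float(wear_waking),
        is_valid=False,
    )
    summary.is_valid = is_valid_day(summary, config)
    return summary


def is_valid_day(summary: DailySummary,
                 config: AccelConfig = AccelConfig()) -> bool:
    """A valid day has >= 10 h of waking wear and >= 200 min of sleep."""
    return (summary.wear_waking_min >= config.min_wear_waking
            and summary.sleep_min >= config.min_sleep)


def day_type_of(date) -> str:
    """'weekend' for Saturday/Sunday, else 'weekday'."""
    return "weekend" if pd.Timestamp(date).dayofweek >= 5 else "weekday"


def filter_valid_participants(daily: pd.DataFrame,
                              config: AccelConfig = AccelConfig()) -> list[str]:
    """Participants with >= 4 valid days including >= 1 valid weekend day."""
    included = []
    for pid, grp in daily.groupby("participant_id", sort=True):
        valid = grp[grp["is_valid"]]
        n_weekend = int((valid["day_type"] == "weekend").sum())
        if len(valid) >= config.min_valid_days and n_weekend >= config.min_weekend_days:
            included.append(pid)
    return included


def weighted_time_use(valid_days: pd.DataFrame,
                      config: AccelConfig = AccelConfig()) -> ParticipantTimeUse:
    """5:2 weekday:weekend weighted mean daily minutes for one participant.

    Weighted mean per domain = (5 * weekday mean + 2 * weekend mean) / 7.
    Requires at least one valid weekend day (participants without one
    should already have been excluded).
    """
    if valid_days.empty:
        raise ValueError("no valid days to weight")
    pid = valid_days["participant_id"].iloc[0]
    domains = ["sleep_min", "sedentary_min", "lpa_min", "mvpa_min", "nonwear_min"]
    wd = valid_days[valid_days["day_type"] == "weekday"]
    we = valid_days[valid_days["day_type"] == "weekend"]
    if we.empty:
        raise ValueError(f"participant {pid}: no valid weekend day; "
                         "cannot apply 5:2 weighting")
    w_wd, w_we = config.weekday_weight, config.weekend_weight
    if wd.empty:
        # all valid days fall on weekends; the weekend mean is the only estimate
        means = we[domains].mean()
    else:
        means = (w_wd * wd[domains].mean() + w_we * we[domains].mean()) / (w_wd + w_we)
    return ParticipantTimeUse(
        participant_id=str(pid),
        sleep_min=float(means["sleep_min"]),
        sedentary_min=float(means["sedentary_min"]),
        lpa_min=float(means["lpa_min"]),
        mvpa_min=float(means["mvpa_min"]),
        nonwear_min=float(means["nonwear_min"]),
        n_valid_days=int(len(valid_days)),
        n_valid_weekend_days=int(len(we)),
        mean_sleep_efficiency_pct=float(valid_days["sleep_efficiency_pct"].mean()),
    )


def _parse_clock_minutes(value) -> float | None:
    """'HH:MM' (or minutes-of-day number) -> minutes past midnight."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        if not value.strip():
            return None
        h, mm = value.split(":")
        return int(h) * 60 + int(mm)
    return float(value)


def process_day(magnitudes, diary_row: dict | None,
                participant_id: str, date,
                config: AccelConfig = AccelConfig()) -> DailySummary:
    """Run the full detector chain on one participant-day."""
    nonwear = detect_non_wear(magnitudes, config)
    onset = wake = None
    if diary_row is not None:
        onset = _parse_clock_minutes(diary_row.get("diary_sleep_onset"))
        wake = _parse_clock_minutes(diary_row.get("diary_wake"))
    sleep = detect_sleep_period(magnitudes, onset, wake, config)
    return summarize_day(magnitudes, nonwear, sleep, participant_id, date,
                         day_type_of(date), config)


def process_cohort(epochs: pd.DataFrame, diary: pd.DataFrame | None = None,
                   config: AccelConfig = AccelConfig()
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process an epoch table into daily summaries and weighted time use.

    ``epochs`` is the long-format table (participant_id, timestamp,
    magnitude_gmin) with 1440 rows per participant-day; ``diary`` is the
    optional activity-card table (participant_id, date,
    diary_sleep_onset, diary_wake).  Returns the per-day summary table
    and the per-participant weighted time-use table restricted to
    participants meeting the inclusion rule.
    """
    ep = epochs.copy()
    ts = pd.to_datetime(ep["timestamp"])
    ep["date"] = ts.dt.date.astype(str)
    ep["minute"] = ts.dt.hour * 60 + ts.dt.minute

    diary_lookup: dict[tuple[str, str], dict] = {}
    if diary is not None:
        for _, row in diary.iterrows():
            diary_lookup[(str(row["participant_id"]), str(row["date"]))] = row.to_dict()

    rows = []
    for (pid, date), grp in ep.groupby(["participant_id", "date"], sort=True):
        if len(grp) != EPOCHS_PER_DAY:
            raise ValueError(
                f"participant {pid} day {date}: expected {EPOCHS_PER_DAY} "
                f"epochs, got {len(grp)}")
        mags = grp.sort_values("minute")["magnitude_gmin"].to_numpy(float)
        drow = diary_lookup.get((str(pid), str(date)))
        rows.append(process_day(mags, drow, str(pid), date, config).as_dict())
    daily = pd.DataFrame(rows)

    included = filter_valid_participants(daily, config)
    ptu_rows = []
    for pid in included:
        valid = daily[(daily["participant_id"] == pid) & daily["is_valid"]]
        ptu_rows.append(weighted_time_use(valid, config).as_dict())
    columns = ["participant_id", "sleep_min", "sedentary_min", "lpa_min",
               "mvpa_min", "nonwear_min", "n_valid_days",
               "n_valid_weekend_days", "mean_sleep_efficiency_pct"]
    participants = pd.DataFrame(ptu_rows, columns=columns)
    return daily, participants
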