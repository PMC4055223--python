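"""Accelerometer epoch-count screening and MVPA summarisation.

Processes 30-second Actigraph-style epoch counts for one participant-week:
restrict to the 08:00-21:00 monitoring window, aggregate to clock-minute
counts, flag non-wear (>=90-min zero runs with a bounded low-count
allowance), classify MVPA epochs against an age-specific count cut point
(>=4 METs), and summarise wear/MVPA per day and per week with the validity
rules (>=546 wear minutes per day; >=4 valid days including >=3 weekdays and
>=1 weekend day per week).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Monitoring-window length in minutes (08:00-21:00 = 13 h).
WINDOW_MINUTES = 780


class EpochFormatError(ValueError):
    """Raised when an epoch CSV violates the expected format."""


class ConfigError(ValueError):
    """Raised for inconsistent screening configuration."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpochSeries:
    """Timestamped 30-s activity counts for one participant.

    Timestamps must be strictly increasing with exact 30-s spacing between
    consecutive records that fall on the same calendar day; counts are
    non-negative integers.
    """

    participant_id: str
    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    epoch_seconds: int = 30

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if len(counts) != len(self.timestamps):
            raise EpochFormatError("timestamps and counts differ in length")
        if len(counts) and counts.min() < 0:
            i = int(np.argmax(counts < 0))
            raise EpochFormatError(f"negative count at record {i}")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        ts = self.timestamps
        if len(ts) > 1:
            deltas = np.diff(ts.asi8) / 1e9
            if (deltas <= 0).any():
                i = int(np.argmax(deltas <= 0))
                raise EpochFormatError(f"non-increasing timestamp at record {i + 1}")
            same_day = ts.normalize()[:-1] == ts.normalize()[1:]
            bad = same_day & (deltas != self.epoch_seconds)
            if bad.any():
                i = int(np.argmax(bad))
                raise EpochFormatError(
                    f"epoch spacing {deltas[i]:.0f}s at record {i + 1}; "
                    f"expected {self.epoch_seconds}s"
                )

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "counts": self.counts})


@dataclass(frozen=True)
class CutpointConfig:
    """How the MVPA count threshold is derived for a given age.

    The default solves an age-based MET regression of the Freedson youth
    lineage, ``METs = b0 + b1*cpm + b2*age + b3*cpm*age``, for the counts
    per minute at which predicted intensity reaches ``met_threshold``
    (>=4 METs marks the youth moderate-intensity floor).  The cpm threshold
    is halved to get the per-30-s-epoch threshold.  A user-supplied
    ``age_cpm_table`` overrides the equation.
    """

    met_threshold: float = 4.0
    b0: float = 2.757
    b1: float = 0.0015
    b2: float = -0.08957
    b3: float = -0.000038
    round_cpm: bool = True
    age_cpm_table: Mapping[int, float] | None = None


@dataclass(frozen=True)
class ScreenConfig:
    """All screening rules in one place (window, non-wear, validity)."""

    window_start: dt.time = dt.time(8, 0)
    window_end: dt.time = dt.time(21, 0)
    nonwear_min_bout: int = 90
    nonwear_allow_max_minutes: int = 2
    nonwear_allow_ceiling: float = 100.0
    valid_day_minutes: float = 546.0  # 0.70 x 780, inclusive
    min_valid_days: int = 4
    min_valid_weekdays: int = 3
    min_valid_weekend: int = 1
    combined_weighting: str = "5/7"  # or "mean"
    cutpoints: CutpointConfig = field(default_factory=CutpointConfig)

    def __post_init__(self) -> None:
        start = _as_minutes(self.window_start)
        end = _as_minutes(self.window_end)
        if start >= end:
            raise ConfigError("window_start must precede window_end")
        if self.combined_weighting not in {"5/7", "mean"}:
            raise ConfigError("combined_weighting must be '5/7' or 'mean'")


@dataclass
class DaySummary:
    """Wear/MVPA outcomes of one monitored day within the window."""

    date: dt.date
    is_weekend: bool
    wear_minutes: float
    mvpa_minutes: float
    pct_mvpa: float | None  # None when wear_minutes == 0
    counts_per_minute_mean: float | None
    valid: bool


@dataclass
class PersonSummary:
    """Weekly wear/MVPA outcomes and week-validity for one participant."""

    participant_id: str
    valid_days: int
    weekday_valid: int
    weekend_valid: int
    pct_mvpa_weekday: float | None
    pct_mvpa_weekend: float | None
    pct_mvpa_combined: float | None
    mvpa_min_daily_mean: float | None
    wear_minutes_daily_mean: float | None
    cpm_daily_mean: float | None
    week_valid: bool


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_epoch_csv(series: EpochSeries, path: str | Path) -> None:
    """Write an epoch series in the package CSV layout (header comments with
    participant id and epoch length, then ``timestamp,counts`` rows)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# participant_id: {series.participant_id}\n")
        fh.write(f"# epoch_seconds: {series.epoch_seconds}\n")
        fh.write("timestamp,counts\n")
        for ts, c in zip(series.timestamps, series.counts):
            fh.write(f"{ts.isoformat()},{int(c)}\n")


def read_epoch_csv(path: str | Path, skip_device_header: bool = False) -> EpochSeries:
    """Read an epoch CSV, validating format row by row.

    Malformed rows are reported with their 1-based line number.  With
    ``skip_device_header`` an Actigraph-export-style preamble (lines before
    the first ``timestamp,counts`` header) is skipped.
    """
    path = Path(path)
    participant_id = path.stem
    epoch_seconds = 30
    rows: list[tuple[str, str, int]] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip().lower()
                    if key == "participant_id":
                        participant_id = val.strip()
                    elif key == "epoch_seconds":
                        epoch_seconds = int(val.strip())
                continue
            if line.lower().startswith("timestamp"):
                header_seen = True
                continue
            if not header_seen:
                if skip_device_header:
                    continue
                raise EpochFormatError(f"{path}:{lineno}: data before header row")
            parts = line.split(",")
            if len(parts) != 2:
                raise EpochFormatError(f"{path}:{lineno}: expected 2 fields")
            rows.append((parts[0], parts[1], lineno))

    ts_list, count_list = [], []
    for ts_str, c_str, lineno in rows:
        try:
            ts = pd.Timestamp(ts_str)
        except ValueError as exc:
            raise EpochFormatError(f"{path}:{lineno}: bad timestamp {ts_str!r}") from exc
        try:
            c = int(c_str)
        except ValueError as exc:
            raise EpochFormatError(f"{path}:{lineno}: bad count {c_str!r}") from exc
        if c < 0:
            raise EpochFormatError(f"{path}:{lineno}: negative count {c}")
        ts_list.append(ts)
        count_list.append(c)

    index = pd.DatetimeIndex(ts_list)
    if epoch_seconds != 30:
        raise EpochFormatError(f"{path}: epoch length {epoch_seconds}s; expected 30s")
    if len(index) > 1:
        deltas = np.diff(index.asi8) / 1e9
        same_day = index.normalize()[:-1] == index.normalize()[1:]
        bad = same_day & (deltas != epoch_seconds)
        if bad.any():
            i = int(np.argmax(bad))
            raise EpochFormatError(
                f"{path}:{rows[i + 1][2]}: epoch spacing {deltas[i]:.0f}s; expected 30s"
            )
        if (deltas <= 0).any():
            i = int(np.argmax(deltas <= 0))
            raise EpochFormatError(f"{path}:{rows[i + 1][2]}: non-increasing timestamp")
    return EpochSeries(participant_id, index, np.asarray(count_list), epoch_seconds)


# ---------------------------------------------------------------------------
# Screening operations
# ---------------------------------------------------------------------------


def _as_minutes(t: dt.time) -> int:
    return t.hour * 60 + t.minute


def restrict_day_window(
    series: EpochSeries,
    start: dt.time = dt.time(8, 0),
    end: dt.time = dt.time(21, 0),
) -> EpochSeries:
    """Keep only epochs whose time of day lies in the half-open [start, end)."""
    if _as_minutes(start) >= _as_minutes(end):
        raise ConfigError("window start must precede end")
    tod = (
        series.timestamps.hour * 3600
        + series.timestamps.minute * 60
        + series.timestamps.second
    )
    lo = _as_minutes(start) * 60
    hi = _as_minutes(end) * 60
    keep = (tod >= lo) & (tod < hi)
    return EpochSeries(
        series.participant_id,
        series.timestamps[keep],
        series.counts[np.asarray(keep)],
        series.epoch_seconds,
    )


def to_minute_counts(series: EpochSeries) -> pd.Series:
    """Sum 30-s epoch pairs into clock-minute counts (cpm).

    Only minutes with both epochs present are emitted; an unpaired epoch is
    dropped from minute aggregation (it is still used for per-epoch MVPA
    classification downstream).  Returns a Series indexed by the minute
    timestamp.
    """
    if len(series) == 0:
        return pd.Series(dtype=np.int64)
    minute = series.timestamps.floor("min")
    df = pd.DataFrame({"minute": minute, "counts": series.counts})
    g = df.groupby("minute", sort=True)["counts"].agg(["sum", "size"])
    complete = g[g["size"] == 2]
    return complete["sum"].astype(np.int64)


def detect_nonwear(
    minute_counts: Sequence[float] | pd.Series,
    min_bout: int = 90,
    allow_max_minutes: int = 2,
    allow_ceiling: float = 100.0,
) -> np.ndarray:
    """Per-minute wear mask (True = worn) for one contiguous day window.

    A maximal run of minutes is non-wear iff it is >= ``min_bout`` minutes
    long and consists of zero-count minutes apart from interruptions, where
    an interruption is a maximal block of <= ``allow_max_minutes``
    consecutive non-zero minutes each with counts in (0, ``allow_ceiling``].
    Any minute above the ceiling, or a non-zero block longer than the
    allowance, terminates the candidate run.
    """
    x = np.asarray(pd.Series(minute_counts).to_numpy(), dtype=float)
    n = len(x)
    if n == 0:
        return np.zeros(0, dtype=bool)

    # Terminators: minutes that can never belong to a non-wear run.
    terminator = x > allow_ceiling
    nonzero = x > 0
    # Maximal consecutive non-zero blocks longer than the allowance terminate.
    if nonzero.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([0], nonzero.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s > allow_max_minutes:
                terminator[s:e] = True

    wear = np.ones(n, dtype=bool)
    ok = ~terminator
    edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_bout:
            wear[s:e] = False
    return wear


def mvpa_cutpoint_cpm(age_years: int, config: CutpointConfig | None = None) -> float:
    """Counts-per-minute cut point at which the age-based MET equation
    reaches the MVPA intensity floor; divide by 2 for the 30-s epoch
    threshold."""
    config = config or CutpointConfig()
    if config.age_cpm_table is not None:
        try:
            return float(config.age_cpm_table[int(age_years)])
        except KeyError as exc:
            raise ConfigError(f"no cut point tabled for age {age_years}") from exc
    denom = config.b1 + config.b3 * age_years
    if abs(denom) < 1e-12:
        raise ConfigError(f"degenerate MET equation at age {age_years}")
    cpm = (config.met_threshold - config.b0 - config.b2 * age_years) / denom
    cpm = max(cpm, 0.0)
    return float(round(cpm)) if config.round_cpm else float(cpm)


def classify_mvpa(
    series: EpochSeries,
    epoch_threshold: float,
    wear_by_minute: pd.Series | None = None,
) -> np.ndarray:
    """Boolean per-epoch MVPA mask: counts >= threshold AND minute is wear.

    ``wear_by_minute`` maps minute timestamps to wear status; epochs whose
    minute is absent from the map (unpaired window-edge epochs) are treated
    as wear.  MVPA minutes = mask.sum() / 2.
    """
    above = series.counts >= epoch_threshold
    if wear_by_minute is None or len(wear_by_minute) == 0:
        return above
    minute = series.timestamps.floor("min")
    wear = wear_by_minute.reindex(minute, fill_value=True).to_numpy(dtype=bool)
    return above & wear


def summarize_day(
    date: dt.date,
    wear_mask: np.ndarray,
    mvpa_mask: np.ndarray,
    minute_counts: pd.Series,
    config: ScreenConfig | None = None,
) -> DaySummary:
    """Fold one day's wear/MVPA masks into a DaySummary.

    ``wear_mask`` is per aggregated minute, ``mvpa_mask`` per epoch.  A day
    is valid iff wear minutes >= ``valid_day_minutes`` (546 = 70% of the
    780-min window, inclusive).
    """
    config = config or ScreenConfig()
    wear_minutes = float(np.count_nonzero(wear_mask))
    mvpa_minutes = float(np.count_nonzero(mvpa_mask)) / 2.0
    if wear_minutes > 0:
        pct = 100.0 * mvpa_minutes / wear_minutes
        cpm_mean = float(np.asarray(minute_counts)[np.asarray(wear_mask)].mean())
    else:
        pct = None
        cpm_mean = None
    return DaySummary(
        date=date,
        is_weekend=date.weekday() >= 5,
        wear_minutes=wear_minutes,
        mvpa_minutes=mvpa_minutes,
        pct_mvpa=pct,
        counts_per_minute_mean=cpm_mean,
        valid=wear_minutes >= config.valid_day_minutes,
    )


def summarize_week(
    participant_id: str,
    days: Iterable[DaySummary],
    config: ScreenConfig | None = None,
) -> PersonSummary:
    """Aggregate DaySummaries into a PersonSummary with the week rule.

    A week is valid iff >=4 valid days with >=3 weekdays and >=1 weekend
    day.  Stratum %MVPA values are means over valid days; the combined value
    weights weekday/weekend 5/7 and 2/7 by default (or an unweighted mean
    over valid days with ``combined_weighting='mean'``).  Invalid weeks carry
    no combined value.
    """
    config = config or ScreenConfig()
    days = list(days)
    valid = [d for d in days if d.valid]
    wk = [d for d in valid if not d.is_weekend]
    we = [d for d in valid if d.is_weekend]
    week_valid = (
        len(valid) >= config.min_valid_days
        and len(wk) >= config.min_valid_weekdays
        and len(we) >= config.min_valid_weekend
    )

    def _mean(vals: list[float | None]) -> float | None:
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    pct_wk = _mean([d.pct_mvpa for d in wk])
    pct_we = _mean([d.pct_mvpa for d in we])
    combined: float | None = None
    if week_valid:
        if config.combined_weighting == "5/7":
            combined = (5.0 * pct_wk + 2.0 * pct_we) / 7.0
        else:
            combined = _mean([d.pct_mvpa for d in valid])
    return PersonSummary(
        participant_id=participant_id,
        valid_days=len(valid),
        weekday_valid=len(wk),
        weekend_valid=len(we),
        pct_mvpa_weekday=pct_wk,
        pct_mvpa_weekend=pct_we,
        pct_mvpa_combined=combined,
        mvpa_min_daily_mean=_mean([d.mvpa_minutes for d in valid]) if valid else None,
        wear_minutes_daily_mean=_mean([d.wear_minutes for d in valid]) if valid else None,
        cpm_daily_mean=_mean([d.counts_per_minute_mean for d in valid]) if valid else None,
        week_valid=week_valid,
    )


def process_series(
    series: EpochSeries,
    age_years: int,
    config: ScreenConfig | None = None,
) -> tuple[PersonSummary, list[DaySummary]]:
    """Full screening pipeline for one participant-week.

    Window restriction -> minute aggregation -> non-wear detection -> MVPA
    classification at the age-specific cut point -> daily and weekly
    summaries.
    """
    config = config or ScreenConfig()
    windowed = restrict_day_window(series, config.window_start, config.window_end)
    cpm_cut = mvpa_cutpoint_cpm(age_years, config.cutpoints)
    epoch_threshold = cpm_cut / 2.0

    day_summaries: list[DaySummary] = []
    if len(windowed) == 0:
        return summarize_week(series.participant_id, [], config), day_summaries
    dates = windowed.timestamps.normalize()
    for day in dates.unique():
        sel = dates == day
        day_series = EpochSeries(
            windowed.participant_id,
            windowed.timestamps[sel],
            windowed.counts[np.asarray(sel)],
            windowed.epoch_seconds,
        )
        minutes = to_minute_counts(day_series)
        wear = detect_nonwear(
            minutes,
            config.nonwear_min_bout,
            config.nonwear_allow_max_minutes,
            config.nonwear_allow_ceiling,
        )
        wear_by_minute = pd.Series(wear, index=minutes.index)
        mvpa = classify_mvpa(day_series, epoch_threshold, wear_by_minute)
        day_summaries.append(
            summarize_day(day.date(), wear, mvpa, minutes, config)
        )
    person = summarize_week(series.participant_id, day_summaries, config)
    return person, day_summaries


def person_summaries_frame(people: Iterable[PersonSummary]) -> pd.DataFrame:
    """Tabulate PersonSummaries for merging with roster/PAQ tables."""
    return pd.DataFrame([vars(p) for p in people])
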