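"""Synthetic cohorts, PAQ responses, and epoch-count traces.

Generates data with the statistical structure the calibration analysis
assumes, so every downstream stage (screening, scoring, fitting,
validation) is testable without external data.  A cohort of 8-14-year-olds
is drawn with an age-graded PAQ distribution (younger children score
higher); each participant's true daily %MVPA follows the linear calibration
model

    %MVPA = b0 + b_sex*sex + b_age*age + b_paq*PAQ + eps,

with Gaussian residuals truncated at zero (percentages cannot be negative).
Epoch traces realise that %MVPA as contiguous MVPA bouts inside the
08:00-21:00 monitoring window, with light activity elsewhere and optional
all-zero non-wear blocks of at least 90 min (the minimum the screening
rules can detect).  Counts are schematic, not biomechanically realistic.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import paq as paq_mod
from .accel import WINDOW_MINUTES, EpochSeries, mvpa_cutpoint_cpm, write_epoch_csv
from .published import PUBLISHED_COEFFICIENTS, PUBLISHED_RMSE, Coefficients

#: Monday anchoring the simulated wear week.
WEEK_START = dt.date(2010, 3, 1)

#: Age at or below which the child form (PAQ-C) is administered.
PAQ_C_MAX_AGE = 11


class GenerationError(ValueError):
    """Raised for unsatisfiable generation requests."""


@dataclass(frozen=True)
class CohortParams:
    """Generating parameters for a synthetic cohort.

    Defaults reproduce the observed cohort structure: n = 148 youths aged
    8-14 (51% boys), PAQ means falling from ~3.4 at age 8 to ~2.7 at age 14
    (SD 0.7), true %MVPA generated from the published calibration
    coefficients with residual SD 2.54, and a wear schedule averaging
    ~754 min/day (two days a week carry a 90-min non-wear block).
    ``pct_mvpa_day_sd`` is the within-person day-to-day SD of daily %MVPA.
    """

    n_participants: int = 148
    age_range: tuple[int, int] = (8, 14)
    prop_male: float = 76 / 148
    prop_spring: float = 0.55
    paq_sd: float = 0.7
    residual_sd_pct: float = PUBLISHED_RMSE
    coefficients: Coefficients = PUBLISHED_COEFFICIENTS
    pct_mvpa_day_sd: float = 2.0
    nonwear_days: int = 2
    nonwear_block_minutes: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise GenerationError("need at least 2 participants (sample is split downstream)")
        for name in ("prop_male", "prop_spring"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0,1]")
        if self.paq_sd <= 0 or self.residual_sd_pct <= 0:
            raise GenerationError("paq_sd and residual_sd_pct must be positive")
        lo, hi = self.age_range
        if not (8 <= lo <= hi <= 14):
            raise GenerationError(f"age_range {self.age_range} outside [8,14]")
        if self.pct_mvpa_day_sd < 0:
            raise GenerationError("pct_mvpa_day_sd must be non-negative")
        if self.nonwear_days and self.nonwear_block_minutes < 90:
            raise GenerationError("non-wear blocks shorter than 90 min are undetectable")

    def paq_mean(self, age: int) -> float:
        """Age-specific mean of the true PAQ score (younger = higher)."""
        return float(np.clip(3.2 - 0.111 * (age - 9.7), 1.0, 5.0))


@dataclass
class DaySchedule:
    """One scheduled monitoring day: wear intervals and MVPA bouts, in
    minutes relative to the 08:00 window start."""

    date: dt.date
    wear_intervals: list[tuple[int, int]]
    mvpa_bouts: list[tuple[int, int]]  # (start_minute, n_epochs)
    pct_mvpa_day: float

    @property
    def wear_minutes(self) -> int:
        return sum(e - s for s, e in self.wear_intervals)


@dataclass
class TrueActivityProfile:
    """Ground truth for one simulated participant."""

    participant_id: str
    sex_code: int  # 1 = male, 2 = female
    age_years: int
    form: str
    season: str  # "fall" | "spring"
    paq_true: float
    pct_mvpa_true: float
    daily_schedule: list[DaySchedule] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex_code not in (1, 2):
            raise GenerationError(f"sex_code {self.sex_code} not in {{1,2}}")
        if not 1.0 <= self.paq_true <= 5.0:
            raise GenerationError(f"paq_true {self.paq_true} outside [1,5]")
        if self.pct_mvpa_true < 0:
            raise GenerationError("pct_mvpa_true must be non-negative")


def expected_pct_mvpa(
    sex_code: int, age_years: float, paq: float, coefficients: Coefficients = PUBLISHED_COEFFICIENTS
) -> float:
    """Noise-free mean of the generating model (not floored)."""
    c = coefficients
    return c.intercept + c.sex * sex_code + c.age * age_years + c.paq * paq


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _place_bouts(
    intervals: list[tuple[int, int]], total_epochs: int
) -> list[tuple[int, int]]:
    """Spread `total_epochs` of MVPA over wear intervals as contiguous bouts.

    Bouts are at most 20 min (40 epochs) and evenly spaced within each
    interval; allocation across intervals is proportional to their length.
    """
    if total_epochs <= 0:
        return []
    lengths = np.array([e - s for s, e in intervals], dtype=float)
    total_wear = lengths.sum()
    # largest-remainder proportional allocation of epochs to intervals
    raw = total_epochs * lengths / total_wear
    alloc = np.floor(raw).astype(int)
    rem = total_epochs - alloc.sum()
    order = np.argsort(-(raw - alloc))
    alloc[order[:rem]] += 1

    bouts: list[tuple[int, int]] = []
    for (s, e), n_ep in zip(intervals, alloc):
        if n_ep <= 0:
            continue
        cap_min = e - s
        if n_ep > 2 * cap_min:
            raise GenerationError("requested MVPA exceeds scheduled wear time")
        n_b = max(1, int(np.ceil(n_ep / 40)))
        sizes = [n_ep // n_b] * n_b
        for i in range(n_ep - sum(sizes)):
            sizes[i] += 1
        seg = cap_min / n_b
        placed = []
        ok = True
        for j, size in enumerate(sizes):
            b_min = int(np.ceil(size / 2))
            start = s + int(j * seg + (seg - b_min) / 2)
            if start < s or start + b_min > e or (placed and start < placed[-1]):
                ok = False
                break
            placed.append(start + b_min)
            bouts.append((start, size))
        if not ok:
            # fall back to sequential packing with 1-min gaps
            bouts = [b for b in bouts if not (s <= b[0] < e)]
            cursor = s
            for size in sizes:
                b_min = int(np.ceil(size / 2))
                if cursor + b_min > e:
                    raise GenerationError("requested MVPA exceeds scheduled wear time")
                bouts.append((cursor, size))
                cursor += b_min + 1
    return sorted(bouts)


def _schedule_week(
    rng: np.random.Generator, day_pcts: np.ndarray, params: CohortParams
) -> list[DaySchedule]:
    nonwear = rng.choice(7, size=params.nonwear_days, replace=False) if params.nonwear_days else []
    schedule = []
    for d in range(7):
        date = WEEK_START + dt.timedelta(days=d)
        if d in nonwear:
            block = params.nonwear_block_minutes
            start = int(rng.integers(60, WINDOW_MINUTES - block - 60))
            intervals = [(0, start), (start + block, WINDOW_MINUTES)]
        else:
            intervals = [(0, WINDOW_MINUTES)]
        wear_min = sum(e - s for s, e in intervals)
        pct = float(day_pcts[d])
        n_epochs = int(round(pct / 100.0 * wear_min * 2))
        bouts = _place_bouts(intervals, n_epochs)
        schedule.append(DaySchedule(date, intervals, bouts, pct))
    return schedule


def generate_cohort(params: CohortParams) -> list[TrueActivityProfile]:
    """Draw a synthetic cohort; deterministic given ``params.seed``.

    Ages are uniform integers over ``age_range``; true PAQ scores are
    normal truncated to [1,5] with age-specific means; true %MVPA is the
    linear model mean plus N(0, residual_sd) noise, floored at 0.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.age_range
    n = params.n_participants
    profiles: list[TrueActivityProfile] = []
    child_seeds = np.random.SeedSequence(params.seed).spawn(n)
    for i in range(n):
        age = int(rng.integers(lo, hi + 1))
        sex = 1 if rng.random() < params.prop_male else 2
        season = "spring" if rng.random() < params.prop_spring else "fall"
        mu = params.paq_mean(age)
        a, b = (1.0 - mu) / params.paq_sd, (5.0 - mu) / params.paq_sd
        paq_true = float(
            stats.truncnorm.rvs(a, b, loc=mu, scale=params.paq_sd, random_state=rng)
        )
        mean_pct = expected_pct_mvpa(sex, age, paq_true, params.coefficients)
        pct_true = max(0.0, mean_pct + rng.normal(0.0, params.residual_sd_pct))
        day_pcts = np.maximum(
            0.0, pct_true + rng.normal(0.0, params.pct_mvpa_day_sd, size=7)
        )
        profile = TrueActivityProfile(
            participant_id=f"P{i + 1:04d}",
            sex_code=sex,
            age_years=age,
            form=paq_mod.FORM_CHILD if age <= PAQ_C_MAX_AGE else paq_mod.FORM_ADOLESCENT,
            season=season,
            paq_true=paq_true,
            pct_mvpa_true=pct_true,
            daily_schedule=_schedule_week(rng, day_pcts, params),
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
        )
        profiles.append(profile)
    return profiles


# ---------------------------------------------------------------------------
# Epoch traces
# ---------------------------------------------------------------------------


def generate_epoch_trace(
    profile: TrueActivityProfile,
    cutpoint_cpm: float | None = None,
    light_cpm_range: tuple[int, int] = (150, 400),
) -> EpochSeries:
    """Realise a profile's schedule as 7 days of 30-s epoch counts.

    Non-wear intervals are all-zero; MVPA bout minutes carry counts strictly
    above ``cutpoint_cpm`` (default: the age-specific cut point); other wear
    minutes carry light activity in (100, cutpoint) cpm so they can neither
    be absorbed into a non-wear allowance nor classified as MVPA.
    """
    if not profile.daily_schedule:
        raise GenerationError("profile has no scheduled days")
    if cutpoint_cpm is None:
        cutpoint_cpm = mvpa_cutpoint_cpm(profile.age_years)
    if cutpoint_cpm <= 0:
        raise GenerationError("cutpoint_cpm must be positive")
    lo, hi = light_cpm_range
    if not 100 < lo < hi < cutpoint_cpm:
        raise GenerationError(
            f"light_cpm_range {light_cpm_range} must lie inside (100, {cutpoint_cpm})"
        )
    rng = np.random.default_rng([profile.seed, 1])
    mvpa_epoch_base = int(np.ceil(cutpoint_cpm / 2.0)) + 100

    all_ts: list[pd.Timestamp] = []
    all_counts: list[np.ndarray] = []
    for day in profile.daily_schedule:
        n_ep = WINDOW_MINUTES * 2
        counts = np.zeros(n_ep, dtype=np.int64)
        for s, e in day.wear_intervals:
            counts[2 * s : 2 * e] = rng.integers(lo // 2, hi // 2 + 1, size=2 * (e - s))
        scheduled = sum(n for _, n in day.mvpa_bouts)
        if scheduled > 2 * day.wear_minutes:
            raise GenerationError("requested MVPA exceeds scheduled wear time")
        for start_min, n in day.mvpa_bouts:
            counts[2 * start_min : 2 * start_min + n] = mvpa_epoch_base + rng.integers(
                0, 100, size=n
            )
        base = pd.Timestamp(dt.datetime.combine(day.date, dt.time(8, 0)))
        all_ts.extend(base + pd.to_timedelta(np.arange(n_ep) * 30, unit="s"))
        all_counts.append(counts)
    return EpochSeries(
        profile.participant_id,
        pd.DatetimeIndex(all_ts),
        np.concatenate(all_counts),
    )


def interruption_fixture(
    zeros_before: int = 50,
    interrupt_minutes: int = 2,
    interrupt_cpm: int = 50,
    zeros_after: int = 48,
    flank_minutes: int = 200,
    flank_cpm: int = 500,
) -> np.ndarray:
    """Minute-count array with an allowance-style interruption inside a zero
    run, flanked by active wear — for non-wear edge-case tests."""
    return np.concatenate(
        [
            np.full(flank_minutes, flank_cpm),
            np.zeros(zeros_before),
            np.full(interrupt_minutes, interrupt_cpm),
            np.zeros(zeros_after),
            np.full(flank_minutes, flank_cpm),
        ]
    ).astype(np.int64)


# ---------------------------------------------------------------------------
# PAQ item generation
# ---------------------------------------------------------------------------


def generate_paq_items(
    profile: TrueActivityProfile,
    n_items: int = 10,
    item_noise_sd: float = 0.5,
    seed: int | None = None,
) -> paq_mod.PAQResponse:
    """Generate 1-5 integer item responses whose mean tracks ``paq_true``.

    ``n_items`` is the checklist length; the form's scored items are always
    produced.  Each response is round(paq_true + N(0, sd)) clipped to [1,5].
    """
    if n_items < 1:
        raise GenerationError("n_items must be >= 1")
    if item_noise_sd < 0:
        raise GenerationError("item_noise_sd must be non-negative")
    rng = np.random.default_rng([profile.seed, 2] if seed is None else seed)

    def draw(k: int) -> np.ndarray:
        raw = profile.paq_true + rng.normal(0.0, item_noise_sd, size=k)
        return np.clip(np.rint(raw), 1, 5).astype(int)

    checklist = draw(n_items).tolist()
    names = paq_mod.required_items(profile.form)
    item_scores = dict(zip(names, draw(len(names)).tolist()))
    return paq_mod.PAQResponse(profile.participant_id, profile.form, checklist, item_scores)


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------


def roster_frame(profiles: Sequence[TrueActivityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "sex_code": [p.sex_code for p in profiles],
            "age_years": [p.age_years for p in profiles],
            "form": [p.form for p in profiles],
            "season": [p.season for p in profiles],
        }
    )


def write_cohort_dataset(
    profiles: Sequence[TrueActivityProfile],
    outdir: str | Path,
    n_items: int = 10,
    item_noise_sd: float = 0.3,
) -> dict[str, Path]:
    """Write roster.csv, paq_items.csv, and per-participant epoch CSVs in the
    formats read by the screening and scoring stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    epochs_dir = outdir / "epochs"
    epochs_dir.mkdir(exist_ok=True)
    roster_path = outdir / "roster.csv"
    roster_frame(profiles).to_csv(roster_path, index=False)
    responses = [
        generate_paq_items(p, n_items=n_items, item_noise_sd=item_noise_sd)
        for p in profiles
    ]
    paq_path = outdir / "paq_items.csv"
    paq_mod.write_paq_csv(responses, paq_path)
    for p in profiles:
        write_epoch_csv(generate_epoch_trace(p), epochs_dir / f"{p.participant_id}.csv")
    return {"roster": roster_path, "paq": paq_path, "epochs": epochs_dir}
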