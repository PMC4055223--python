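"""Hold-out validation: prediction, weekly-minute conversion, agreement.

Applies a calibration equation to held-out participants, converts daily
%MVPA to weekly MVPA minutes on a 5,460-minute awake-time base (13 h/day x
7 days), and evaluates agreement against the accelerometer criterion:
paired-difference bias with t-based 95% CI, Bland-Altman limits of
agreement (mean difference +/- 1.96 SD), correlations, and classification
against the 420 min/week (60 min/day) activity guideline with
sensitivity/specificity and a rank-based (Mann-Whitney) AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .accel import WINDOW_MINUTES, PersonSummary
from .published import (
    AWAKE_MINUTES_PER_WEEK,
    GUIDELINE_WEEKLY_MINUTES,
    PUBLISHED_COEFFICIENTS,
    Coefficients,
)


@dataclass
class PredictionRecord:
    """Predicted vs observed weekly MVPA for one validation participant."""

    participant_id: str
    predicted_pct_mvpa: float
    predicted_weekly_minutes: float
    observed_weekly_minutes: float

    @property
    def difference(self) -> float:
        """Predicted minus observed weekly minutes."""
        return self.predicted_weekly_minutes - self.observed_weekly_minutes


@dataclass
class AgreementReport:
    """Group- and individual-level agreement between the two instruments."""

    n: int
    mean_bias: float
    sd_diff: float
    se_bias: float
    ci95: tuple[float, float]
    loa: tuple[float, float]
    paired_t: float
    paired_df: int
    paired_p: float
    pearson_r: float | None = None
    spearman_r: float | None = None
    r_squared_val: float | None = None
    rmse_val: float | None = None


@dataclass
class ClassificationReport:
    """Guideline (420 min/week) classification agreement."""

    threshold_weekly_minutes: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    auc: float | None


def predict_pct_mvpa(
    sex_code,
    age_years,
    paq_score,
    coefficients: Coefficients = PUBLISHED_COEFFICIENTS,
) -> np.ndarray:
    """Predicted daily %MVPA from the calibration equation, floored at 0.

    The PAQ score is rounded to one decimal place before entering the
    equation (its stated input convention).  Ages outside 8-14 are allowed
    with a warning — the equation was built on that range.
    """
    sex = np.asarray(sex_code, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if not np.all(np.isin(sex, (1.0, 2.0))):
        raise ValueError("sex_code must be 1 (male) or 2 (female)")
    if np.any((age < 8) | (age > 14)):
        warnings.warn("age outside the 8-14 y calibration range", stacklevel=2)
    paq = np.round(np.asarray(paq_score, dtype=float), 1)
    c = coefficients
    raw = c.intercept + c.sex * sex + c.age * age + c.paq * paq
    return np.maximum(raw, 0.0)


def pct_to_weekly_minutes(pct, awake_minutes_per_week: float = AWAKE_MINUTES_PER_WEEK):
    """Convert daily %MVPA into weekly MVPA minutes on the awake-time base."""
    return np.asarray(pct, dtype=float) / 100.0 * awake_minutes_per_week


def observed_weekly_minutes(
    person: PersonSummary,
    awake_minutes_per_week: float = AWAKE_MINUTES_PER_WEEK,
    mode: str = "pct",
) -> float:
    """Accelerometer-based weekly MVPA minutes for one participant.

    ``pct`` (default) converts the combined %MVPA through the same
    5,460-minute base as the predictions, putting both instruments on one
    time scale; ``minutes`` scales the mean daily MVPA minutes by 7.  The
    two agree exactly when wear time fills the 780-min window.
    """
    if mode == "pct":
        if person.pct_mvpa_combined is None:
            raise ValueError(f"{person.participant_id}: no combined %MVPA (invalid week)")
        return person.pct_mvpa_combined / 100.0 * awake_minutes_per_week
    if mode == "minutes":
        if person.mvpa_min_daily_mean is None:
            raise ValueError(f"{person.participant_id}: no daily MVPA mean (invalid week)")
        return person.mvpa_min_daily_mean * 7.0
    raise ValueError(f"unknown mode {mode!r}")


def bland_altman(differences) -> AgreementReport:
    """Agreement statistics from paired differences (predicted - observed).

    LOA uses the fixed 1.96 multiplier; the 95% CI of the mean bias uses the
    t quantile with n-1 df; SD uses the n-1 denominator.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError(f"need >= 3 paired differences, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    tq = stats.t.ppf(0.975, n - 1)
    if se > 0:
        t_stat = mean / se
        p = float(2 * stats.t.sf(abs(t_stat), n - 1))
    else:
        t_stat = 0.0 if mean == 0 else float(np.inf) * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
    return AgreementReport(
        n=n,
        mean_bias=mean,
        sd_diff=sd,
        se_bias=se,
        ci95=(mean - tq * se, mean + tq * se),
        loa=(mean - 1.96 * sd, mean + 1.96 * sd),
        paired_t=float(t_stat),
        paired_df=n - 1,
        paired_p=p,
    )


def agreement_report(predicted, observed) -> AgreementReport:
    """Full agreement battery for paired predicted/observed weekly minutes.

    Adds Pearson/Spearman correlations and the R^2 and residual RMSE of the
    simple regression of observed on predicted to the Bland-Altman core.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    rep = bland_altman(pred - obs)
    n = rep.n
    if np.std(pred) > 0 and np.std(obs) > 0:
        rep.pearson_r = float(stats.pearsonr(pred, obs)[0])
        rep.spearman_r = float(stats.spearmanr(pred, obs)[0])
        X = np.column_stack([np.ones(n), pred])
        beta, *_ = np.linalg.lstsq(X, obs, rcond=None)
        resid = obs - X @ beta
        sse = float(resid @ resid)
        sst = float(((obs - obs.mean()) ** 2).sum())
        rep.r_squared_val = 1.0 - sse / sst if sst > 0 else None
        rep.rmse_val = float(np.sqrt(sse / (n - 2)))
    return rep


def guideline_classification(
    predicted_minutes,
    observed_minutes,
    threshold: float = GUIDELINE_WEEKLY_MINUTES,
) -> ClassificationReport:
    """Classify participants against the weekly guideline on both
    instruments and score the questionnaire against accelerometer truth.

    "Active" means weekly minutes >= threshold.  Sensitivity is the percent
    of accelerometer-active participants predicted active; specificity the
    percent of accelerometer-inactive predicted inactive.  AUC is the
    Mann-Whitney rank statistic of predicted minutes against the
    accelerometer class (ties count one half); it is None, with the report
    flagging it, when the observations are all one class.
    """
    pred = np.asarray(predicted_minutes, dtype=float)
    obs = np.asarray(observed_minutes, dtype=float)
    truth = obs >= threshold
    call = pred >= threshold
    tp = int(np.sum(truth & call))
    fn = int(np.sum(truth & ~call))
    tn = int(np.sum(~truth & ~call))
    fp = int(np.sum(~truth & call))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else None
    n1, n0 = int(truth.sum()), int((~truth).sum())
    if n1 and n0:
        ranks = stats.rankdata(pred)
        auc = float((ranks[truth].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    else:
        auc = None
    return ClassificationReport(threshold, tp, fp, tn, fn, sens, spec, auc)


def prediction_table(
    roster: pd.DataFrame,
    coefficients: Coefficients = PUBLISHED_COEFFICIENTS,
    awake_minutes_per_week: float = AWAKE_MINUTES_PER_WEEK,
) -> pd.DataFrame:
    """Per-participant predictions for a merged analysis table with columns
    participant_id, sex_code, age_years, paq_score, pct_mvpa_combined."""
    pct = predict_pct_mvpa(
        roster["sex_code"], roster["age_years"], roster["paq_score"], coefficients
    )
    out = roster[["participant_id"]].copy()
    out["predicted_pct_mvpa"] = pct
    out["predicted_weekly_minutes"] = pct_to_weekly_minutes(pct, awake_minutes_per_week)
    out["observed_weekly_minutes"] = (
        roster["pct_mvpa_combined"].to_numpy(dtype=float) / 100.0 * awake_minutes_per_week
    )
    out["difference"] = out["predicted_weekly_minutes"] - out["observed_weekly_minutes"]
    return out
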