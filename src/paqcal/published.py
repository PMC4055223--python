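"""Published calibration constants.

The calibration equation maps sex, age and the PAQ summary score onto the
daily percentage of accelerometer wear time spent in MVPA:

    %MVPA = 14.56 - 0.98*sex - 0.84*age + 1.01*PAQ

with sex coded 1 = male, 2 = female, age in whole years (8-14), and the PAQ
score given to one decimal place.  Shipping these coefficients lets the
prediction/validation stages run with zero fitting.
"""

from __future__ import annotations

from typing import NamedTuple


class Coefficients(NamedTuple):
    """Linear calibration coefficients, %MVPA units."""

    intercept: float
    sex: float
    age: float
    paq: float


#: Published calibration coefficients (intercept, sex, age, PAQ).
PUBLISHED_COEFFICIENTS = Coefficients(intercept=14.56, sex=-0.98, age=-0.84, paq=1.01)

#: Residual root-mean-square error of the published calibration model (%MVPA).
PUBLISHED_RMSE = 2.54

#: Weekly awake minutes used to convert daily %MVPA into weekly MVPA minutes
#: (13 waking hours/day x 7 days).
AWAKE_MINUTES_PER_WEEK = 5460

#: Weekly MVPA minutes meeting the youth guideline (60 min/day x 7).
GUIDELINE_WEEKLY_MINUTES = 420

#: Sex coding used throughout: 1 = male, 2 = female.
SEX_MALE = 1
SEX_FEMALE = 2
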