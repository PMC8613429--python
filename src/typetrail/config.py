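"""Configuration models for the synthetic cohort generator and the analysis pipeline.

All knobs that the pipeline or generator exposes live here as pydantic models so
that a JSON config file is validated (unknown keys rejected, ranges checked)
before any stage runs.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: Canonical fixed-effect column names of the analysis-ready model table.
#: Every coefficient map is keyed by these names (plus ``intercept``).
FIXED_TERM_COLUMNS = (
    "age_z",
    "log_wrong_moves_z",
    "time_of_day_z",
    "practice_z",
    "period_z",
    "practice_period_z",
    "diagnosis_z",
    "hdrs_grand_z",
    "hdrs_subject_z",
    "ikd_grand_z",
    "ikd_subject_z",
)

#: Fixed-effect coefficients used by the generator by default: the fitted
#: estimates of the full model (Model 3) on the original study's scale, i.e.
#: the response is ln(completion seconds) and every covariate is z-scored.
DEFAULT_FIXED_COEFFS: dict[str, float] = {
    "intercept": 2.898,
    "age_z": 0.008,
    "log_wrong_moves_z": 0.220,
    "time_of_day_z": 0.013,
    "practice_z": -0.069,
    "period_z": -0.039,
    "practice_period_z": 0.041,
    "diagnosis_z": -0.180,
    "hdrs_grand_z": 0.189,
    "hdrs_subject_z": 0.038,
    "ikd_grand_z": 0.189,
    "ikd_subject_z": 0.032,
}

#: Random-effect variances (per-subject intercept and slopes) and the column
#: of the model table each random term multiplies.
DEFAULT_RANDOM_VARIANCES: dict[str, float] = {
    "intercept": 0.010,
    "practice_slope": 0.0003,
    "period_slope": 0.002,
    "interaction_slope": 0.002,
}

RANDOM_TERM_COLUMNS: dict[str, Optional[str]] = {
    "intercept": None,
    "practice_slope": "practice_z",
    "period_slope": "period_z",
    "interaction_slope": "practice_period_z",
}

DEFAULT_RESIDUAL_VARIANCE = 0.058

#: Multinomial over keypress categories (no text content is ever generated).
KEY_CATEGORY_PROBS: dict[str, float] = {
    "alphanumeric": 0.70,
    "space": 0.12,
    "backspace": 0.08,
    "punctuation": 0.05,
    "autocorrection": 0.03,
    "suggestion": 0.015,
    "other": 0.005,
}


class DayRange(BaseModel):
    """Inclusive range of study days (day 1 = first study day)."""

    model_config = ConfigDict(extra="forbid")

    start: int = Field(ge=1)
    end: int = Field(ge=1)

    @model_validator(mode="after")
    def _ordered(self) -> "DayRange":
        if self.end < self.start:
            raise ValueError(f"day range end ({self.end}) before start ({self.start})")
        return self

    @property
    def days(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:  # number of days in the range
        return self.end - self.start + 1


class MoodParams(BaseModel):
    """Weekly clinician-rating process for one diagnostic group.

    A subject's trait score is drawn once (normal, truncated at 0); the weekly
    series is trait + AR(1) fluctuation, rounded and clipped to the scale range.
    """

    model_config = ConfigDict(extra="forbid")

    trait_mean: float
    trait_sd: float = Field(ge=0)
    ar_rho: float = Field(default=0.6, ge=0, le=1)
    ar_sd: float = Field(default=1.0, ge=0)


class IkdParams(BaseModel):
    """Keypress-stream shape: traits, session structure, within-session dispersion.

    ``trait_median_s`` is the typical per-subject median inter-key delay;
    subject traits are lognormal around it. Within a session delays are
    lognormal with median trait x daily multiplier and log-SD ``session_log_sd``,
    clipped below the session cutoff so that all within-session transitions are
    shorter than 8 s by construction. Between-session gaps are always > 8 s.
    """

    model_config = ConfigDict(extra="forbid")

    trait_median_s: float = Field(default=0.25, gt=0)
    trait_log_sd: float = Field(default=0.25, ge=0)
    daily_log_sd: float = Field(default=0.10, ge=0)
    session_log_sd: float = Field(default=0.5, ge=0)
    sessions_per_day: float = Field(default=8.0, ge=0)
    keys_per_session: float = Field(default=25.0, ge=0)
    session_cutoff_s: float = Field(default=8.0, gt=0)
    day_start_hour: float = Field(default=7.0, ge=0, lt=24)
    day_end_hour: float = Field(default=22.0, ge=0, le=24)

    @model_validator(mode="after")
    def _hours(self) -> "IkdParams":
        if self.day_end_hour <= self.day_start_hour:
            raise ValueError("day_end_hour must exceed day_start_hour")
        return self


class GeneratorConfig(BaseModel):
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the design of the source study: 8 controls and 11
    individuals with bipolar disorder, twice-daily digital trail-making tests
    on study days 1-17 and 45-56 (a four-week break in between), weekly
    HDRS-17 (plus YMRS for the bipolar group) ratings, continuous keypress
    collection, and enough scheduled-test skipping that subjects average about
    31 completed tests.
    """

    model_config = ConfigDict(extra="forbid")

    n_control: int = Field(default=8, ge=0)
    n_bipolar: int = Field(default=11, ge=0)
    period1: DayRange = DayRange(start=1, end=17)
    period2: DayRange = DayRange(start=45, end=56)
    study_start: dt.date = dt.date(2021, 1, 4)
    missingness: float = Field(default=0.47, ge=0, le=1)

    fixed_coeffs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_FIXED_COEFFS))
    random_variances: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_RANDOM_VARIANCES)
    )
    residual_variance: float = Field(default=DEFAULT_RESIDUAL_VARIANCE, ge=0)

    hdrs_control: MoodParams = MoodParams(trait_mean=1.02, trait_sd=1.49, ar_sd=0.8)
    hdrs_bipolar: MoodParams = MoodParams(trait_mean=12.68, trait_sd=7.80, ar_sd=2.5)
    ymrs_bipolar: MoodParams = MoodParams(trait_mean=6.00, trait_sd=3.80, ar_sd=1.5)

    ikd: IkdParams = IkdParams()

    age_mean: float = Field(default=46.6, gt=0)
    age_sd: float = Field(default=10.6, ge=0)
    prob_male: float = Field(default=6 / 19, ge=0, le=1)

    wrong_moves_rate: float = Field(default=1.5, ge=0)
    wrong_moves_rate_log_sd: float = Field(default=0.5, ge=0)

    slot_hours: tuple[float, float] = (9.0, 21.0)  # morning, evening preset times
    slot_jitter_min: float = Field(default=30.0, ge=0)

    #: paper-test scores share the subject-level latent predictors of the
    #: digital scores; this is the extra modality noise SD on the log scale.
    ptmt_modality_sd: float = Field(default=0.11, ge=0)

    seed: int = 0

    @field_validator("random_variances")
    @classmethod
    def _variances(cls, v: dict[str, float]) -> dict[str, float]:
        for name, value in v.items():
            if name not in RANDOM_TERM_COLUMNS:
                raise ValueError(f"unknown random term {name!r}")
            if value < 0:
                raise ValueError(f"random variance {name!r} must be >= 0, got {value}")
        for name in RANDOM_TERM_COLUMNS:
            if name not in v:
                raise ValueError(f"random_variances missing term {name!r}")
        return v

    @field_validator("fixed_coeffs")
    @classmethod
    def _coeffs(cls, v: dict[str, float]) -> dict[str, float]:
        allowed = set(FIXED_TERM_COLUMNS) | {"intercept"}
        unknown = set(v) - allowed
        if unknown:
            raise ValueError(f"unknown fixed_coeffs names: {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _periods_disjoint(self) -> "GeneratorConfig":
        if self.period2.start <= self.period1.end:
            raise ValueError(
                f"period ranges must be disjoint and ordered: period1 ends day "
                f"{self.period1.end}, period2 starts day {self.period2.start}"
            )
        if not self.slot_hours[0] < self.slot_hours[1]:
            raise ValueError("slot_hours: morning slot must precede evening slot")
        return self


class FeatureOptions(BaseModel):
    """Typing-feature extraction knobs."""

    model_config = ConfigDict(extra="forbid")

    timezone: str = "UTC"
    session_cutoff_s: float = Field(default=8.0, gt=0)
    min_valid_transitions: int = Field(default=20, ge=1)
    min_keypresses: int = Field(default=20, ge=0)
    min_tests_per_subject: int = Field(default=6, ge=1)
    #: include non-character events (backspace, autocorrection, ...) in delays
    all_categories: bool = True


class AssemblyOptions(BaseModel):
    """Model-table construction knobs."""

    model_config = ConfigDict(extra="forbid")

    timezone: str = "UTC"
    period1: DayRange = DayRange(start=1, end=17)
    period2: DayRange = DayRange(start=45, end=56)
    #: study day 1; inferred as the earliest test date in the dataset when None
    study_start: Optional[dt.date] = None
    #: z-score dummy-coded terms (diagnosis, period, time of day) like the rest
    z_score_dummies: bool = True
    #: practice day counting: calendar days within period ("calendar_day") or
    #: the subject's administration index within period ("administration")
    practice_unit: str = "calendar_day"

    @field_validator("practice_unit")
    @classmethod
    def _unit(cls, v: str) -> str:
        if v not in ("calendar_day", "administration"):
            raise ValueError("practice_unit must be 'calendar_day' or 'administration'")
        return v

    @model_validator(mode="after")
    def _periods(self) -> "AssemblyOptions":
        if self.period2.start <= self.period1.end:
            raise ValueError("period ranges must be disjoint and ordered")
        return self


class ModelOptions(BaseModel):
    """LMM fitting knobs."""

    model_config = ConfigDict(extra="forbid")

    models: list[int] = Field(default_factory=lambda: [1, 2, 3])
    re_structure: str = "unstructured"
    restarts: int = Field(default=5, ge=1)
    tol: float = Field(default=1e-8, gt=0)
    seed: Optional[int] = None

    @field_validator("re_structure")
    @classmethod
    def _structure(cls, v: str) -> str:
        if v not in ("unstructured", "diagonal"):
            raise ValueError("re_structure must be 'unstructured' or 'diagonal'")
        return v

    @field_validator("models")
    @classmethod
    def _models(cls, v: list[int]) -> list[int]:
        if any(m not in (1, 2, 3, 4, 5) for m in v):
            raise ValueError("models must be drawn from 1..5")
        if v != sorted(v):
            raise ValueError("models must be in increasing order")
        return v


class RunConfig(BaseModel):
    """Top-level pipeline configuration (one JSON file, per-stage sections)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    timezone: str = "UTC"
    simulate: GeneratorConfig = Field(default_factory=GeneratorConfig)
    features: FeatureOptions = Field(default_factory=FeatureOptions)
    assemble: AssemblyOptions = Field(default_factory=AssemblyOptions)
    model: ModelOptions = Field(default_factory=ModelOptions)
    reliability_alpha: float = Field(default=0.05, gt=0, lt=1)
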