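"""Simulation configuration: study-like default conditions for the synthetic cohort.

The defaults emulate a ~814-participant validation sub-cohort with up to three
24-h recalls per person, 11 eating occasions per recall day, and four analyzed
meals (breakfast, lunch, afternoon snack, dinner).  Variance components are on
the log-intake scale and default to the values implied by the published
intra-class correlations for each outcome.  Occasion labels and their clock
times are package-invented defaults (the original occasion roster is not
public) and are declared here, in the config, rather than claimed from any
source.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigurationError

OUTCOMES: tuple[str, ...] = ("energy", "carbohydrate", "protein", "fat")

DEFAULT_MEALS: tuple[str, ...] = ("breakfast", "lunch", "afternoon_snack", "dinner")


@dataclass(frozen=True)
class Occasion:
    """One of the 11 eating-occasion slots of a recall day.

    ``mean_minutes``/``sd_minutes`` parameterize the truncated-normal clock
    time (minutes since midnight); ``meal_type`` maps the slot to one of the
    four analyzed meals or to ``"other"``.
    """

    label: str
    mean_minutes: int
    sd_minutes: int
    meal_type: str


DEFAULT_OCCASIONS: tuple[Occasion, ...] = (
    Occasion("before_breakfast", 360, 30, "other"),
    Occasion("breakfast", 465, 40, "breakfast"),
    Occasion("second_breakfast", 570, 35, "other"),
    Occasion("mid_morning_snack", 650, 30, "other"),
    Occasion("lunch", 750, 40, "lunch"),
    Occasion("early_afternoon_snack", 870, 30, "other"),
    Occasion("afternoon_snack", 945, 35, "afternoon_snack"),
    Occasion("late_afternoon_snack", 1020, 25, "other"),
    Occasion("dinner", 1125, 40, "dinner"),
    Occasion("after_dinner_snack", 1230, 30, "other"),
    Occasion("late_night_snack", 1335, 30, "other"),
)

# Per-outcome log-scale variance components implied by the published ICC
# shares (meal 39/25/47/33 %, participant 0/3/0/3 % for energy, carbohydrate,
# protein, fat respectively).
DEFAULT_VAR_PARTICIPANT = {"energy": 0.000, "carbohydrate": 0.024, "protein": 0.000, "fat": 0.015}
DEFAULT_VAR_MEALCELL = {"energy": 0.273, "carbohydrate": 0.200, "protein": 0.282, "fat": 0.165}
DEFAULT_VAR_OCCASION = {"energy": 0.427, "carbohydrate": 0.576, "protein": 0.318, "fat": 0.320}

# Published frequencies of zero intakes (energy-free beverages etc.).
DEFAULT_ZERO_RATE = {"energy": 0.028, "carbohydrate": 0.027, "protein": 0.033, "fat": 0.049}

# Log-scale grand means chosen so exp() lands near typical per-occasion
# intakes (kcal / g); they do not affect any scale-invariant statistic.
DEFAULT_GRAND_MEAN = {
    "energy": math.log(430.0),
    "carbohydrate": math.log(40.0),
    "protein": math.log(15.0),
    "fat": math.log(20.0),
}

DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"M": 0.505, "W": 0.495},
    "smoking": {"never": 0.463, "former": 0.434, "current": 0.103},
    "education": {"no_training": 0.328, "technical_college": 0.230, "university": 0.442},
    "occupation": {"full_time": 0.305, "part_time": 0.075, "no_job_retired": 0.620},
}

# Continuous participant covariates: (mean, sd, lower, upper) truncated normal.
DEFAULT_CONTINUOUS_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "age": (65.5, 8.4, 47.0, 81.0),
    "bmi": (27.5, 4.4, 16.0, 50.0),
    "physical_activity": (22.6, 14.7, 0.5, 90.0),
}

# Names the effect maps may use.  Within (intake-level) covariates are dummy
# or numeric columns of the occasion table; between covariates come from the
# participant table (dummies expanded against their reference categories).
WITHIN_COVARIATE_NAMES: tuple[str, ...] = (
    "weekend",
    "season_summer",
    "special_day",
    "prior_interval",
    "place_work",
    "place_restaurant",
    "place_other",
)
BETWEEN_COVARIATE_NAMES: tuple[str, ...] = (
    "sex_W",
    "age",
    "bmi",
    "physical_activity",
    "education_technical_college",
    "education_university",
    "occupation_full_time",
    "occupation_part_time",
    "smoking_former",
    "smoking_current",
)

# Modest covariate effects (log scale) in the published directions: place of
# meal and weekend dominate the intake level, sex dominates the participant
# level.  Magnitudes are package choices sized to yield level R² in the low
# ranges the study reports.
DEFAULT_BETA_WITHIN = {
    "weekend": 0.06,
    "season_summer": 0.01,
    "special_day": 0.06,
    "prior_interval": 0.015,
    "place_work": -0.20,
    "place_restaurant": 0.12,
    "place_other": 0.02,
}
DEFAULT_BETA_BETWEEN = {
    "sex_W": -0.22,
    "age": 0.003,
    "bmi": 0.004,
    "physical_activity": 0.0,
    "education_technical_college": 0.0,
    "education_university": 0.01,
    "occupation_full_time": 0.0,
    "occupation_part_time": -0.02,
    "smoking_former": 0.02,
    "smoking_current": 0.05,
}


def _as_outcome_map(value, name: str) -> dict[str, float]:
    """Broadcast a scalar to all outcomes, or validate a per-outcome mapping."""
    if isinstance(value, Mapping):
        unknown = set(value) - set(OUTCOMES)
        if unknown:
            raise ConfigurationError(f"{name}: unknown outcome(s) {sorted(unknown)}")
        return {o: float(value.get(o, 0.0)) for o in OUTCOMES}
    return {o: float(value) for o in OUTCOMES}


@dataclass
class SimulationConfig:
    """Full description of one synthetic-cohort draw.

    Variances, grand means and zero rates may be a scalar (applied to every
    outcome) or a per-outcome mapping.  ``beta_within``/``beta_between`` map
    covariate (dummy) names to log-scale effects per unit.
    """

    n_participants: int = 814
    n_days: int = 3
    meal_types: tuple[str, ...] = DEFAULT_MEALS
    occasions: tuple[Occasion, ...] = DEFAULT_OCCASIONS
    var_participant: object = field(default_factory=lambda: dict(DEFAULT_VAR_PARTICIPANT))
    var_mealcell: object = field(default_factory=lambda: dict(DEFAULT_VAR_MEALCELL))
    var_occasion: object = field(default_factory=lambda: dict(DEFAULT_VAR_OCCASION))
    grand_mean: object = field(default_factory=lambda: dict(DEFAULT_GRAND_MEAN))
    meal_offsets: dict[str, float] = field(default_factory=dict)
    beta_within: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_WITHIN))
    beta_between: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA_BETWEEN))
    zero_rate: object = field(default_factory=lambda: dict(DEFAULT_ZERO_RATE))
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_MARGINALS.items()}
    )
    continuous_marginals: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS_MARGINALS)
    )
    meal_attendance: float = 0.95
    snack_rate: float = 0.25
    missing_meal_rate: float = 0.01
    place_probs: dict[str, float] = field(
        default_factory=lambda: {"home": 0.75, "work": 0.12, "restaurant": 0.08, "other": 0.05}
    )
    special_day_rate: float = 0.08
    season_summer_rate: float = 0.5
    calendar_days: int = 120
    include_tee: bool = True
    tee_coverage: float = 682 / 814
    misreport_under_rate: float = 0.396
    misreport_over_rate: float = 0.078
    seed: int = 0

    # -- normalized accessors -------------------------------------------------
    def var_participant_map(self) -> dict[str, float]:
        return _as_outcome_map(self.var_participant, "var_participant")

    def var_mealcell_map(self) -> dict[str, float]:
        return _as_outcome_map(self.var_mealcell, "var_mealcell")

    def var_occasion_map(self) -> dict[str, float]:
        return _as_outcome_map(self.var_occasion, "var_occasion")

    def grand_mean_map(self) -> dict[str, float]:
        return _as_outcome_map(self.grand_mean, "grand_mean")

    def zero_rate_map(self) -> dict[str, float]:
        return _as_outcome_map(self.zero_rate, "zero_rate")

    def occasion_labels(self) -> tuple[str, ...]:
        return tuple(o.label for o in self.occasions)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if self.n_days < 1:
            raise ConfigurationError("n_days must be >= 1")
        for name, m in (
            ("var_participant", self.var_participant_map()),
            ("var_mealcell", self.var_mealcell_map()),
            ("var_occasion", self.var_occasion_map()),
        ):
            for o, v in m.items():
                if v < 0:
                    raise ConfigurationError(f"{name}[{o}] must be >= 0, got {v}")
        for o, z in self.zero_rate_map().items():
            if not 0.0 <= z < 0.5:
                raise ConfigurationError(f"zero_rate[{o}] must be in [0, 0.5), got {z}")
        for cov, freqs in self.covariate_marginals.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigurationError(
                    f"covariate_marginals[{cov}] frequencies sum to {total}, not 1"
                )
            if any(p < 0 for p in freqs.values()):
                raise ConfigurationError(f"covariate_marginals[{cov}] has negative frequency")
        occasion_meals = {o.meal_type for o in self.occasions}
        missing = set(self.meal_types) - occasion_meals
        if missing:
            raise ConfigurationError(
                f"meal_types {sorted(missing)} have no occasion mapped to them"
            )
        if len(set(self.occasion_labels())) != len(self.occasions):
            raise ConfigurationError("occasion labels must be unique")
        unknown_w = set(self.beta_within) - set(WITHIN_COVARIATE_NAMES)
        if unknown_w:
            raise ConfigurationError(f"beta_within: unknown covariate(s) {sorted(unknown_w)}")
        unknown_b = set(self.beta_between) - set(BETWEEN_COVARIATE_NAMES)
        if unknown_b:
            raise ConfigurationError(f"beta_between: unknown covariate(s) {sorted(unknown_b)}")
        unknown_m = set(self.meal_offsets) - occasion_meals
        if unknown_m:
            raise ConfigurationError(f"meal_offsets: unknown meal type(s) {sorted(unknown_m)}")
        for rate_name in (
            "meal_attendance",
            "snack_rate",
            "missing_meal_rate",
            "tee_coverage",
            "special_day_rate",
            "season_summer_rate",
        ):
            v = getattr(self, rate_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{rate_name} must be in [0, 1], got {v}")
        if self.misreport_under_rate + self.misreport_over_rate > 1.0:
            raise ConfigurationError("misreporting rates exceed 1")
        total_place = sum(self.place_probs.values())
        if abs(total_place - 1.0) > 1e-8:
            raise ConfigurationError(f"place_probs sum to {total_place}, not 1")

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["occasions"] = [dataclasses.asdict(o) for o in self.occasions]
        d["meal_types"] = list(self.meal_types)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "occasions" in d:
            d["occasions"] = tuple(
                o if isinstance(o, Occasion) else Occasion(**o) for o in d["occasions"]
            )
        if "meal_types" in d:
            d["meal_types"] = tuple(d["meal_types"])
        if "continuous_marginals" in d:
            d["continuous_marginals"] = {
                k: tuple(v) for k, v in d["continuous_marginals"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
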