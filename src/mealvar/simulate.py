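"""Synthetic hierarchical 24-h-recall data with known ground truth.

The generative model for each outcome on the log scale is

    log y_imt = mu + mu_m + x_imt' beta_W + w_i' beta_B + u_i + v_im + e_imt

with participant intercepts u_i ~ N(0, var_participant), participant-by-meal
intercepts v_im ~ N(0, var_mealcell) and occasion noise
e_imt ~ N(0, var_occasion).  Intakes are exp() of the linear predictor; zeros
(energy-free beverages) are injected per outcome by replacing the simulated
positive value with exactly 0 at the configured rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    BETWEEN_COVARIATE_NAMES,
    OUTCOMES,
    WITHIN_COVARIATE_NAMES,
    SimulationConfig,
)
from .errors import ValidationError

PARTICIPANT_COLUMNS = [
    "participant_id",
    "sex",
    "age",
    "bmi",
    "education",
    "occupation",
    "smoking",
    "physical_activity",
]

INTAKE_COLUMNS = [
    "participant_id",
    "day_index",
    "day_offset",
    "occasion_label",
    "clock_time",
    "meal_type",
    "energy",
    "carbohydrate",
    "protein",
    "fat",
    "weekend",
    "season",
    "special_day",
    "place",
]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_participants(config: SimulationConfig) -> pd.DataFrame:
    """Draw the participant table with Table-1-like covariate marginals."""
    config.validate()
    n = config.n_participants
    if n == 0:
        return pd.DataFrame(columns=PARTICIPANT_COLUMNS)
    rng = _rng(config, 0)
    width = max(4, len(str(n)))
    data: dict[str, object] = {
        "participant_id": [f"P{i + 1:0{width}d}" for i in range(n)]
    }
    for cov in ("sex", "smoking", "education", "occupation"):
        freqs = config.covariate_marginals[cov]
        cats = list(freqs)
        data[cov] = rng.choice(cats, size=n, p=[freqs[c] for c in cats])
    for cov, (mean, sd, lo, hi) in config.continuous_marginals.items():
        data[cov] = _truncnorm(rng, mean, sd, lo, hi, n)
    return pd.DataFrame(data)[PARTICIPANT_COLUMNS]


def _between_design(participants: pd.DataFrame) -> pd.DataFrame:
    """Numeric participant-level design with the declared dummy names."""
    p = participants
    return pd.DataFrame(
        {
            "sex_W": (p["sex"] == "W").astype(float),
            "age": p["age"].astype(float),
            "bmi": p["bmi"].astype(float),
            "physical_activity": p["physical_activity"].astype(float),
            "education_technical_college": (p["education"] == "technical_college").astype(float),
            "education_university": (p["education"] == "university").astype(float),
            "occupation_full_time": (p["occupation"] == "full_time").astype(float),
            "occupation_part_time": (p["occupation"] == "part_time").astype(float),
            "smoking_former": (p["smoking"] == "former").astype(float),
            "smoking_current": (p["smoking"] == "current").astype(float),
        },
        index=p.index,
    )


def _clock_bounds(config: SimulationConfig):
    """Truncation bounds per occasion chosen so clock times cannot cross the
    neighbouring occasions' midpoints (keeps within-day times monotone)."""
    means = np.array([o.mean_minutes for o in config.occasions], float)
    lo = np.empty_like(means)
    hi = np.empty_like(means)
    for k, occ in enumerate(config.occasions):
        lo[k] = max(0.0, means[k] - 2.5 * occ.sd_minutes)
        hi[k] = min(1439.0, means[k] + 2.5 * occ.sd_minutes)
        if k > 0:
            lo[k] = max(lo[k], (means[k - 1] + means[k]) / 2 + 1)
        if k + 1 < len(means):
            hi[k] = min(hi[k], (means[k] + means[k + 1]) / 2 - 1)
    return lo, hi


def _draw_reporting_bias(config: SimulationConfig, n: int):
    """Participant-specific multiplicative reporting-bias factors.

    Drawn on a dedicated seed stream so `simulate_intake` (which applies the
    factor to reported intakes) and `assign_tee` (which needs the same factor
    to back out the unbiased energy requirement) see identical values.
    """
    rng = _rng(config, 3)
    p_under = config.misreport_under_rate
    p_over = config.misreport_over_rate
    cls = rng.choice(
        ["under", "plausible", "over"],
        size=n,
        p=[p_under, 1.0 - p_under - p_over, p_over],
    )
    factor = np.empty(n)
    factor[cls == "under"] = rng.uniform(0.55, 0.78, (cls == "under").sum())
    factor[cls == "plausible"] = rng.uniform(0.84, 1.16, (cls == "plausible").sum())
    factor[cls == "over"] = rng.uniform(1.22, 1.55, (cls == "over").sum())
    return cls, factor


def simulate_intake(participants: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Draw the long occasion-level intake table for the given participants.

    When TEE is enabled, reported intakes additionally carry the
    participant-specific reporting-bias factor (under-reporters report less
    than they eat), making energy misreporting a real between-person signal.
    """
    config.validate()
    if len(participants) == 0:
        raise ValidationError("participants table is empty")
    rng = _rng(config, 1)
    G = len(participants)
    D = config.n_days
    occasions = config.occasions
    K = len(occasions)
    ids = participants["participant_id"].to_numpy()

    # Recall days: D distinct calendar-day offsets per participant, sorted.
    day_offsets = np.empty((G, D), dtype=int)
    for i in range(G):
        day_offsets[i] = np.sort(rng.choice(config.calendar_days, size=D, replace=False))

    # Which (participant, day, occasion) is consumed.
    meal_types = np.array([o.meal_type for o in occasions])
    is_meal = meal_types != "other"
    # A participant may never report a given analyzed meal type.
    never = {
        m: rng.random(G) < config.missing_meal_rate for m in config.meal_types
    }
    consume = np.empty((G, D, K), dtype=bool)
    for k, occ in enumerate(occasions):
        p = config.meal_attendance if is_meal[k] else config.snack_rate
        consume[:, :, k] = rng.random((G, D)) < p
        if occ.meal_type in never:
            consume[never[occ.meal_type], :, k] = False

    gi, di, ki = np.nonzero(consume)
    n_rows = gi.size
    if n_rows == 0:
        return pd.DataFrame(columns=INTAKE_COLUMNS)

    lo, hi = _clock_bounds(config)
    clock = np.empty(n_rows)
    for k, occ in enumerate(occasions):
        mask = ki == k
        m = int(mask.sum())
        if m:
            clock[mask] = _truncnorm(rng, occ.mean_minutes, occ.sd_minutes, lo[k], hi[k], m)
    clock = np.floor(clock).astype(int)

    offsets = day_offsets[gi, di]
    weekday = offsets % 7  # day offset 0 is a Monday
    weekend = weekday >= 5
    season_summer_day = rng.random((G, D)) < config.season_summer_rate
    season = np.where(season_summer_day[gi, di], "summer", "winter")
    special = rng.random(n_rows) < config.special_day_rate
    place_cats = list(config.place_probs)
    place = rng.choice(place_cats, size=n_rows, p=[config.place_probs[c] for c in place_cats])

    table = pd.DataFrame(
        {
            "participant_id": ids[gi],
            "day_index": di + 1,
            "day_offset": offsets,
            "occasion_label": np.array([o.label for o in occasions])[ki],
            "clock_time": clock,
            "meal_type": meal_types[ki],
            "weekend": np.where(weekend, "y", "n"),
            "season": season,
            "special_day": np.where(special, "y", "n"),
            "place": place,
        }
    )
    table = table.sort_values(
        ["participant_id", "day_offset", "clock_time"], kind="mergesort"
    ).reset_index(drop=True)

    # Within-level numeric design (prior interval computed with the same rule
    # the preprocessing step applies, so downstream recomputation matches).
    from .preprocess import compute_prior_interval

    with_pi = compute_prior_interval(table, occasion_order=config.occasion_labels())
    x_within = pd.DataFrame(
        {
            "weekend": (table["weekend"] == "y").astype(float),
            "season_summer": (table["season"] == "summer").astype(float),
            "special_day": (table["special_day"] == "y").astype(float),
            "prior_interval": with_pi["prior_interval"].fillna(0.0),
            "place_work": (table["place"] == "work").astype(float),
            "place_restaurant": (table["place"] == "restaurant").astype(float),
            "place_other": (table["place"] == "other").astype(float),
        }
    )
    eta_within = np.zeros(len(table))
    for name, beta in config.beta_within.items():
        eta_within += beta * x_within[name].to_numpy()

    w = _between_design(participants.reset_index(drop=True))
    eta_between_p = np.zeros(G)
    for name, beta in config.beta_between.items():
        eta_between_p += beta * w[name].to_numpy()
    pid_codes = pd.Categorical(table["participant_id"], categories=ids).codes
    eta_between = eta_between_p[pid_codes]

    cell_types = list(dict.fromkeys(meal_types))  # unique, ordered
    cell_index = {m: j for j, m in enumerate(cell_types)}
    cell_codes = np.array([cell_index[m] for m in table["meal_type"]])

    vp = config.var_participant_map()
    vm = config.var_mealcell_map()
    ve = config.var_occasion_map()
    gm = config.grand_mean_map()
    zr = config.zero_rate_map()
    offsets_map = {m: config.meal_offsets.get(m, 0.0) for m in cell_types}
    meal_offset_row = np.array([offsets_map[m] for m in table["meal_type"]])

    if config.include_tee:
        _, bias_factor = _draw_reporting_bias(config, G)
        log_bias = np.log(bias_factor)[pid_codes]
    else:
        log_bias = 0.0

    for outcome in OUTCOMES:
        u = rng.normal(0.0, np.sqrt(vp[outcome]), G)
        v = rng.normal(0.0, np.sqrt(vm[outcome]), (G, len(cell_types)))
        e = rng.normal(0.0, np.sqrt(ve[outcome]), len(table))
        log_y = (
            gm[outcome]
            + meal_offset_row
            + eta_within
            + eta_between
            + log_bias
            + u[pid_codes]
            + v[pid_codes, cell_codes]
            + e
        )
        y = np.exp(log_y)
        zeros = rng.random(len(table)) < zr[outcome]
        y[zeros] = 0.0
        table[outcome] = y

    return table[INTAKE_COLUMNS]


def assign_tee(
    participants: pd.DataFrame, intake: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Attach total energy expenditure with an injected reporting-bias class.

    The reporting-bias factor b applied to this cohort's reported intakes is
    re-derived from the shared seed stream; TEE is the participant's unbiased
    energy requirement, i.e. mean daily reported energy divided by b, so the
    EI/TEE ratio recovers b exactly.  The true factor is kept in
    ``true_ei_tee_bias`` for recovery tests; TEE is missing for the uncovered
    fraction of participants.
    """
    from .misreport import usual_ei

    rng = _rng(config, 2)
    out = participants.copy()
    ei = usual_ei(intake)
    ei = ei.reindex(out["participant_id"]).to_numpy()

    _, factor = _draw_reporting_bias(config, len(out))
    covered = rng.random(len(out)) < config.tee_coverage
    tee = np.where(covered & np.isfinite(ei), ei / factor, np.nan)
    out["tee_kcal"] = tee
    out["true_ei_tee_bias"] = factor
    return out


def simulate_dataset(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participants + intake in one call; attaches TEE when configured."""
    participants = simulate_participants(config)
    intake = simulate_intake(participants, config)
    if config.include_tee:
        participants = assign_tee(participants, intake, config)
    return participants, intake
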