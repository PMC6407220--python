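"""From raw occasion-level recalls to the analysis table.

Covers the prior-interval construction (hours since the previous consumed
occasion among all 11 slots), retention of the four analyzed meals,
outcome-specific zero exclusion with log transform, and the descriptive
intake summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DEFAULT_MEALS, DEFAULT_OCCASIONS, OUTCOMES
from .errors import ConfigurationError, ValidationError

_DEFAULT_OCCASION_ORDER = tuple(o.label for o in DEFAULT_OCCASIONS)


def _day_column(table: pd.DataFrame) -> str:
    # Absolute calendar offsets are preferred; recall-number indices are a
    # fallback where day k and k+1 are treated as consecutive calendar days.
    return "day_offset" if "day_offset" in table.columns else "day_index"


def _check_monotone(table: pd.DataFrame, occasion_order) -> None:
    order = {label: k for k, label in enumerate(occasion_order)}
    known = table["occasion_label"].map(order)
    sub = table[known.notna()].assign(_order=known[known.notna()])
    day = _day_column(table)
    bad: list[str] = []
    for (pid, d), grp in sub.groupby(["participant_id", day], sort=False):
        g = grp.sort_values("_order", kind="mergesort")
        t = g["clock_time"].to_numpy()
        steps = np.diff(t)
        if (steps <= 0).any():
            for j in np.nonzero(steps <= 0)[0]:
                bad.append(
                    f"participant {pid} day {d}: {g['occasion_label'].iloc[j + 1]} at "
                    f"{t[j + 1]} min not after {g['occasion_label'].iloc[j]} at {t[j]} min"
                )
        if len(bad) >= 20:
            break
    if bad:
        raise ValidationError(
            "non-monotone occasion times within a day:\n" + "\n".join(bad[:20])
        )


def compute_prior_interval(
    table: pd.DataFrame, occasion_order=_DEFAULT_OCCASION_ORDER
) -> pd.DataFrame:
    """Hours since the participant's previous consumed occasion.

    All occasions count as antecedents.  The gap crosses midnight to the
    previous recall day only when the two days are consecutive calendar days;
    a participant's first observed occasion (or one following a multi-day gap)
    has no defined interval and is left missing.  Rows whose occasion labels
    appear in ``occasion_order`` are validated for monotone within-day clock
    times; pass ``occasion_order=None`` to skip that check.
    """
    if table.empty:
        out = table.copy()
        out["prior_interval"] = pd.Series(dtype=float)
        return out
    if table["clock_time"].isna().any():
        raise ValidationError("clock_time missing for some consumed occasions")
    if occasion_order is not None:
        _check_monotone(table, occasion_order)

    day = _day_column(table)
    out = table.copy()
    order = out.sort_values(
        ["participant_id", day, "clock_time"], kind="mergesort"
    ).index
    pid = out.loc[order, "participant_id"].to_numpy()
    days = out.loc[order, day].to_numpy(float)
    minutes = days * 1440.0 + out.loc[order, "clock_time"].to_numpy(float)

    prior = np.full(len(out), np.nan)
    same = pid[1:] == pid[:-1]
    day_gap = days[1:] - days[:-1]
    ok = same & (day_gap <= 1)
    prior[1:][ok] = (minutes[1:] - minutes[:-1])[ok] / 60.0
    out.loc[order, "prior_interval"] = prior
    return out


def select_meals(table: pd.DataFrame, meals=DEFAULT_MEALS) -> pd.DataFrame:
    """Retain only rows of the analyzed meal types."""
    if table.empty:
        return table.copy()
    known = set(table["meal_type"].unique()) | set(DEFAULT_MEALS) | {"other"}
    unknown = set(meals) - known
    if unknown:
        raise ConfigurationError(f"unknown meal label(s): {sorted(unknown)}")
    return table[table["meal_type"].isin(meals)].copy()


def exclude_zeros_log(table: pd.DataFrame, outcome: str) -> tuple[pd.DataFrame, int]:
    """Drop zero intakes of ``outcome`` and add its natural-log column.

    Exclusion is outcome-specific: a row removed for fat may remain in the
    energy analysis.  Idempotent — if ``log_<outcome>`` already exists the
    table is returned unchanged with 0 exclusions.
    """
    if outcome not in OUTCOMES:
        raise ConfigurationError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    log_col = f"log_{outcome}"
    if log_col in table.columns:
        return table.copy(), 0
    values = table[outcome]
    if (values < 0).any():
        raise ValidationError(f"negative {outcome} intake found")
    keep = values > 0
    n_excluded = int((~keep).sum())
    out = table[keep].copy()
    out[log_col] = np.log(out[outcome].to_numpy())
    return out, n_excluded


def _mean_sd(values: pd.Series) -> tuple[float, float, int]:
    n = int(values.notna().sum())
    mean = float(values.mean()) if n else np.nan
    sd = 0.0 if n == 1 else float(values.std(ddof=1)) if n else np.nan
    return mean, sd, n


def summarize_intake(
    table: pd.DataFrame, participants: pd.DataFrame, meals=DEFAULT_MEALS
) -> pd.DataFrame:
    """Mean ± SD of energy/macronutrient intake by day and by meal, by sex.

    Day-level rows summarize each participant's mean daily total over all
    occasions; meal-level rows summarize per-occasion intakes of the four
    analyzed meals.
    """
    missing = set(table["participant_id"]) - set(participants["participant_id"])
    if missing:
        raise ValidationError(
            f"{len(missing)} participant id(s) in the intake table are missing "
            f"from the participant table"
        )
    sex = participants.set_index("participant_id")["sex"]
    groups = {"all": None, "men": "M", "women": "W"}

    records = []
    day_totals = (
        table.groupby(["participant_id", "day_index"], sort=False)[list(OUTCOMES)]
        .sum()
        .groupby("participant_id")
        .mean()
    )
    day_totals["sex"] = sex.reindex(day_totals.index)
    meal_rows = table[table["meal_type"].isin(meals)].copy()
    meal_rows["sex"] = sex.reindex(meal_rows["participant_id"]).to_numpy()

    for outcome in OUTCOMES:
        for gname, gsex in groups.items():
            sub = day_totals if gsex is None else day_totals[day_totals["sex"] == gsex]
            mean, sd, n = _mean_sd(sub[outcome])
            records.append((outcome, "day", gname, mean, sd, n))
        for meal in meals:
            mr = meal_rows[meal_rows["meal_type"] == meal]
            for gname, gsex in groups.items():
                sub = mr if gsex is None else mr[mr["sex"] == gsex]
                mean, sd, n = _mean_sd(sub[outcome])
                records.append((outcome, meal, gname, mean, sd, n))
    return pd.DataFrame(
        records, columns=["variable", "stratum", "group", "mean", "sd", "n"]
    )
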