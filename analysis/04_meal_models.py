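#!/usr/bin/env python
"""Meal-stratified predictor importance: which intake-level and
participant-level factors explain the intake variation at each meal?

For every outcome and meal the occasion rows are decomposed into pooled
within-participant and between-participant covariance; level-specific
regressions give standardized beta-weights, zero-order correlations, level R²
and Pratt indices (the share of R² attributable to each predictor).
"""

import warnings
from pathlib import Path

import pandas as pd

from mealvar import (
    OUTCOMES,
    compute_prior_interval,
    exclude_zeros_log,
    fit_meal_models,
    results_to_frame,
    select_meals,
)
from mealvar.io import read_intake_csv, read_participants_csv
from mealvar.pipeline import DEFAULT_BETWEEN, DEFAULT_WITHIN

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    participants = read_participants_csv(BASE / "data" / "participants.csv")
    intake = read_intake_csv(BASE / "data" / "intake.csv")
    intake = compute_prior_interval(intake, occasion_order=None)
    meals_only = select_meals(intake)

    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for outcome in OUTCOMES:
            table, _ = exclude_zeros_log(meals_only, outcome)
            results = fit_meal_models(
                table, participants, outcome, DEFAULT_WITHIN, DEFAULT_BETWEEN
            )
            frames.append(results_to_frame(results))
    tidy = pd.concat(frames, ignore_index=True)
    tidy.to_csv(BASE / "meal_models.csv", index=False)

    print("most important predictor per meal and level (energy, Pratt index):")
    energy = tidy[(tidy["outcome"] == "energy") & tidy["pratt"].notna()]
    for (meal, level), grp in energy.groupby(["meal", "level"], sort=False):
        top = grp.loc[grp["pratt"].idxmax()]
        print(
            f"  {meal:>16} {level:>8}: {top['predictor']:<28}"
            f"PI = {100 * top['pratt']:5.1f}%  (level R² = {top['r2']:.3f})"
        )
    print(f"wrote {BASE}/meal_models.csv ({len(tidy)} predictor rows)")


if __name__ == "__main__":
    main()
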