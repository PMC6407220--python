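#!/usr/bin/env python
"""Descriptive tables for the synthetic cohort.

Participant characteristics (categorical frequencies, continuous mean ± SD)
and mean ± SD energy/macronutrient intake by day and by meal, overall and by
sex — the layout a dietary-survey report would print.
"""

from pathlib import Path

import pandas as pd

from mealvar import summarize_intake
from mealvar.io import read_intake_csv, read_participants_csv

BASE = Path(__file__).resolve().parent.parent / "results"


def participant_table(participants: pd.DataFrame) -> pd.DataFrame:
    rows = []
    n = len(participants)
    for col in ("sex", "smoking", "education", "occupation"):
        for cat, count in participants[col].value_counts().items():
            rows.append((col, cat, count, 100 * count / n, None))
    for col in ("age", "bmi", "physical_activity", "tee_kcal"):
        series = participants[col].dropna()
        rows.append((col, "mean_sd", len(series), series.mean(), series.std(ddof=1)))
    return pd.DataFrame(rows, columns=["variable", "category", "n", "value", "sd"])


def main() -> None:
    participants = read_participants_csv(BASE / "data" / "participants.csv")
    intake = read_intake_csv(BASE / "data" / "intake.csv")

    chars = participant_table(participants)
    chars.to_csv(BASE / "participant_characteristics.csv", index=False)

    summary = summarize_intake(intake, participants)
    summary.to_csv(BASE / "intake_summary.csv", index=False)

    day_energy = summary.query("variable == 'energy' and stratum == 'day'")
    print("mean daily energy intake (kcal):")
    for _, row in day_energy.iterrows():
        print(f"  {row['group']:>6}: {row['mean']:7.0f} ± {row['sd']:.0f} (n={row['n']})")
    meal_energy = summary.query("variable == 'energy' and stratum != 'day' and group == 'all'")
    print("mean per-meal energy intake (kcal, all participants):")
    for _, row in meal_energy.iterrows():
        print(f"  {row['stratum']:>16}: {row['mean']:6.0f} ± {row['sd']:.0f}")
    print(f"wrote {BASE}/participant_characteristics.csv, intake_summary.csv")


if __name__ == "__main__":
    main()
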