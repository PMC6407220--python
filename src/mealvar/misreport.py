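"""Energy-misreporting classification from the EI/TEE ratio.

Reported energy intake (EI) is summarized as the naive mean of daily totals
over recall days (a stand-in for usual-intake modelling, labelled as such in
output metadata).  Participants are classified by EI/TEE against the fixed
cutoffs 0.81 and 1.19: strictly below 0.81 is under-reporting, strictly above
1.19 over-reporting, the closed interval in between plausible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

UNDER_CUTOFF = 0.81
OVER_CUTOFF = 1.19

EI_METHOD = "naive mean of daily energy totals over recall days"


def usual_ei(table: pd.DataFrame) -> pd.Series:
    """Per-participant mean daily energy intake (kcal/day) over all occasions."""
    if "energy" not in table.columns or table["energy"].notna().sum() == 0:
        raise ValidationError("no energy data")
    day = "day_index" if "day_index" in table.columns else "day_offset"
    daily = table.groupby(["participant_id", day], sort=False)["energy"].sum()
    ei = daily.groupby("participant_id").mean()
    ei.name = "ei_kcal"
    return ei


def classify_ei_tee(ei, tee):
    """EI/TEE ratio and class: under (< 0.81), over (> 1.19), else plausible.

    Accepts scalars or arrays; missing TEE yields a missing class
    (unclassifiable participant).  Non-positive TEE is a validation error.
    """
    ei_arr = np.asarray(ei, dtype=float)
    tee_arr = np.asarray(tee, dtype=float)
    scalar = ei_arr.ndim == 0
    ei_arr = np.atleast_1d(ei_arr)
    tee_arr = np.atleast_1d(tee_arr)
    if (ei_arr < 0).any():
        raise ValidationError("EI must be >= 0")
    if (tee_arr[np.isfinite(tee_arr)] <= 0).any():
        raise ValidationError("TEE must be > 0")
    ratio = np.where(np.isfinite(tee_arr), ei_arr / tee_arr, np.nan)
    cls = np.where(
        np.isnan(ratio),
        None,
        np.where(ratio < UNDER_CUTOFF, "under", np.where(ratio > OVER_CUTOFF, "over", "plausible")),
    )
    if scalar:
        return cls[0], float(ratio[0])
    return cls, ratio


def add_misreporting(participants: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Augment the participant table with EI, EI/TEE ratio and class columns.

    Participants without TEE are flagged unclassifiable (missing class) and
    are meant to be excluded from the sensitivity model.
    """
    if "tee_kcal" not in participants.columns:
        raise ValidationError("participant table has no tee_kcal column")
    out = participants.copy()
    ei = usual_ei(table).reindex(out["participant_id"])
    out["ei_kcal"] = ei.to_numpy()
    cls, ratio = classify_ei_tee(
        out["ei_kcal"].fillna(0.0).to_numpy(), out["tee_kcal"].to_numpy()
    )
    cls = np.where(out["ei_kcal"].isna().to_numpy(), None, cls)
    ratio = np.where(out["ei_kcal"].isna().to_numpy(), np.nan, ratio)
    out["ei_tee_ratio"] = ratio
    out["misreporting_class"] = pd.array(cls, dtype="string")
    out.attrs["ei_method"] = EI_METHOD
    return out


def classifiable(participants: pd.DataFrame) -> pd.DataFrame:
    """Participants with a defined misreporting class (TEE available)."""
    if "misreporting_class" not in participants.columns:
        raise ValidationError("run add_misreporting first")
    return participants[participants["misreporting_class"].notna()].copy()
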