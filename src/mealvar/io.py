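"""CSV reading/writing for the participant and intake tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

INTAKE_REQUIRED = ("participant_id", "day_index", "occasion_label", "clock_time", "meal_type")
PARTICIPANT_REQUIRED = ("participant_id",)


def _parse_clock(value) -> int:
    """Clock time as minutes since midnight; accepts "HH:MM" or integer minutes."""
    if isinstance(value, str) and ":" in value:
        hh, mm = value.split(":")
        minutes = int(hh) * 60 + int(mm)
    else:
        minutes = int(value)
    if not 0 <= minutes < 1440:
        raise ValidationError(f"clock_time {value!r} outside [0, 1440) minutes")
    return minutes


def read_intake_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in INTAKE_REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"intake CSV missing column(s): {missing}")
    table["clock_time"] = [_parse_clock(v) for v in table["clock_time"]]
    dupes = table.duplicated(["participant_id", "day_index", "occasion_label"])
    if dupes.any():
        raise ValidationError(
            f"duplicate (participant, day, occasion) rows at lines "
            f"{(np.nonzero(dupes.to_numpy())[0] + 2).tolist()[:10]}"
        )
    return table


def read_participants_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"participant CSV missing column(s): {missing}")
    if table["participant_id"].duplicated().any():
        raise ValidationError("participant_id values are not unique")
    return table


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
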