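"""Cluster (participant-level) nonparametric bootstrap with percentile CIs.

Whole participants are drawn with replacement, each carrying all of its
occasion rows; duplicated draws receive distinct surrogate ids so the cluster
structure of the resample matches an ordinary sample of the same size.
Intervals are the 2.5/97.5 empirical percentiles (linear interpolation
between order statistics) over successful replicates; the published contract
uses B = 1000 replicates.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError

logger = logging.getLogger(__name__)

Estimator = Callable[[pd.DataFrame, pd.DataFrame], pd.Series]


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # Independent deterministic sub-stream per replicate: results do not
    # depend on execution order.
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def resample_participants(
    participants: pd.DataFrame, table: pd.DataFrame, seed
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One cluster resample: participants drawn with replacement + their rows."""
    if len(participants) == 0:
        raise ValidationError("participant table is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = participants["participant_id"].to_numpy()
    G = len(ids)
    draws = rng.integers(0, G, size=G)

    new_participants = participants.iloc[draws].copy()
    surrogates = np.array([f"{ids[d]}#{k}" for k, d in enumerate(draws)])
    new_participants["participant_id"] = surrogates
    new_participants = new_participants.reset_index(drop=True)

    groups = table.groupby("participant_id", sort=False).indices
    empty = np.array([], dtype=int)
    idx_blocks = [groups.get(ids[d], empty) for d in draws]
    lens = np.array([len(b) for b in idx_blocks])
    row_idx = np.concatenate(idx_blocks) if lens.sum() else empty
    new_table = table.iloc[row_idx].copy()
    new_table["participant_id"] = np.repeat(surrogates, lens)
    return new_participants, new_table.reset_index(drop=True)


def bootstrap_ci(
    estimator: Estimator,
    participants: pd.DataFrame,
    table: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    max_fail_frac: float = 0.5,
) -> pd.DataFrame:
    """Point estimate + 2.5/97.5 percentile bounds for a vector statistic.

    ``estimator`` maps (participants, table) to a named ``pd.Series``.
    Replicates where estimation raises are dropped from the percentile pool
    and counted in ``n_failed``; more than ``max_fail_frac`` failures is a
    hard error (the statistic is too unstable to summarize).
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    point = estimator(participants, table)
    if not isinstance(point, pd.Series):
        point = pd.Series(point)

    replicates = []
    n_failed = 0
    for b in range(B):
        rng = _replicate_rng(seed, b)
        p_star, t_star = resample_participants(participants, table, rng)
        try:
            rep = estimator(p_star, t_star)
        except Exception as exc:  # noqa: BLE001 - replicate failures are data-driven
            n_failed += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
            continue
        replicates.append(rep)
    if n_failed > max_fail_frac * B:
        raise EstimationError(
            f"{n_failed}/{B} bootstrap replicates failed; statistic too unstable"
        )
    pool = pd.DataFrame(replicates).reindex(columns=point.index)
    lower = pool.quantile(0.025, interpolation="linear")
    upper = pool.quantile(0.975, interpolation="linear")
    return pd.DataFrame(
        {
            "statistic": point.index,
            "estimate": point.to_numpy(),
            "lower": lower.reindex(point.index).to_numpy(),
            "upper": upper.reindex(point.index).to_numpy(),
            "B": B,
            "n_failed": n_failed,
            "seed": seed,
        }
    )


# ---------------------------------------------------------------------------
# Ready-made estimators for the pipeline statistics
# ---------------------------------------------------------------------------

def make_icc_estimator(outcome: str, meals=None) -> Estimator:
    """ICC shares (percent) of the three-level intercept-only ML fit."""
    from .config import DEFAULT_MEALS
    from .preprocess import exclude_zeros_log, select_meals
    from .variance import fit_three_level_ml, icc_shares

    meals = tuple(meals) if meals is not None else DEFAULT_MEALS

    def estimator(participants: pd.DataFrame, table: pd.DataFrame) -> pd.Series:
        sub = select_meals(table, meals)
        sub, _ = exclude_zeros_log(sub, outcome)
        cells = sub["participant_id"].astype(str) + "|" + sub["meal_type"].astype(str)
        vc = fit_three_level_ml(
            sub[f"log_{outcome}"], sub["participant_id"], cells
        )
        shares = icc_shares(vc)
        return pd.Series(
            {f"icc|{outcome}|{k}": 100.0 * v for k, v in shares.items()}
        )

    return estimator


def make_pratt_estimator(
    outcome: str, within_covs, between_covs, meals=None
) -> Estimator:
    """Flattened per-meal per-level beta / r / R² / Pratt statistics."""
    from .config import DEFAULT_MEALS
    from .twolevel import fit_meal_models

    meals = tuple(meals) if meals is not None else DEFAULT_MEALS

    def estimator(participants: pd.DataFrame, table: pd.DataFrame) -> pd.Series:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            results = fit_meal_models(
                table, participants, outcome, within_covs, between_covs, meals=meals
            )
        out = {}
        for res in results:
            key = f"{outcome}|{res.meal}|{res.level}"
            out[f"{key}|r2"] = res.r2
            for pred in res.predictors:
                out[f"{key}|beta|{pred}"] = res.beta[pred]
                out[f"{key}|r|{pred}"] = res.r[pred]
                if res.pratt is not None:
                    out[f"{key}|pratt|{pred}"] = res.pratt[pred]
        return pd.Series(out)

    return estimator
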