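"""Two-level within/between covariance decomposition and Pratt indices.

For occasion rows z_it clustered by participant i, the pooled within-cluster
covariance

    S_PW = sum_i sum_t (z_it - zbar_i)(z_it - zbar_i)' / (N - G)

consistently estimates the within (intake-level) covariance, while the scaled
between matrix

    S_B = sum_i n_i (zbar_i - zbar)(zbar_i - zbar)' / (G - 1),
    Sigma_B = (S_B - S_PW) / c,   c = (N - sum_i n_i^2 / N) / (G - 1)

estimates the covariance of the cluster-level latent means (the closed-form
moment estimator used in multilevel SEM).  Level-specific regressions are
solved directly from the covariance blocks; each predictor's Pratt index
beta_j * r_j / R^2 decomposes the level R^2 additively (negative values flag
suppression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_MEALS
from .errors import EstimationError, ValidationError

# Reference categories for dummy expansion (each non-reference category gets
# its own predictor column).
REFERENCE_LEVELS = {
    "place": "home",
    "smoking": "never",
    "education": "no_training",
    "occupation": "no_job_retired",
    "sex": "M",
    "season": "winter",
    "misreporting_class": "plausible",
}
# y/n flags (weekend, special_day) are coded 1 for "y" with "n" as reference.
_CATEGORY_ORDER = {
    "place": ("work", "restaurant", "other"),
    "smoking": ("former", "current"),
    "education": ("technical_college", "university"),
    "occupation": ("full_time", "part_time"),
    "sex": ("W",),
    "season": ("summer",),
    "misreporting_class": ("under", "over"),
}


@dataclass
class TwoLevelDecomposition:
    s_pw: pd.DataFrame
    s_b: pd.DataFrame
    sigma_b: pd.DataFrame
    c: float
    n_obs: int
    n_clusters: int
    floored: tuple[str, ...] = ()


def decompose_two_level(z: pd.DataFrame, cluster_ids) -> TwoLevelDecomposition:
    """Closed-form moment decomposition of a multivariate occasion table."""
    cluster = np.asarray(cluster_ids)
    if len(cluster) != len(z):
        raise ValidationError("cluster_ids length does not match z")
    values = z.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError("z contains missing values; drop incomplete rows first")
    codes, uniques = pd.factorize(cluster)
    N, p = values.shape
    G = len(uniques)
    if G < 2:
        raise ValidationError("need at least 2 clusters")
    if N - G < 1:
        raise ValidationError("no within-cluster degrees of freedom (all clusters singleton)")

    n_i = np.bincount(codes).astype(float)
    sums = np.zeros((G, p))
    np.add.at(sums, codes, values)
    means = sums / n_i[:, None]

    centered = values - means[codes]
    s_pw = centered.T @ centered / (N - G)

    grand = values.mean(axis=0)
    dev = means - grand
    s_b = (dev * n_i[:, None]).T @ dev / (G - 1)

    c = (N - float(np.sum(n_i**2)) / N) / (G - 1)
    sigma_b = (s_b - s_pw) / c

    cols = list(z.columns)
    floored = []
    for j, name in enumerate(cols):
        if sigma_b[j, j] < 0:
            sigma_b[j, j] = 0.0
            floored.append(name)

    as_df = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return TwoLevelDecomposition(
        as_df(s_pw), as_df(s_b), as_df(sigma_b), float(c), N, G, tuple(floored)
    )


def level_model(
    sigma: pd.DataFrame, outcome: str, predictors: list[str]
) -> tuple[pd.Series, pd.Series, float]:
    """Standardized betas, zero-order correlations and R² from a covariance.

    Solves Sigma_xx b = sigma_xy, then beta_j = b_j * sd(x_j) / sd(y) and
    r_j = cov(x_j, y) / (sd(x_j) sd(y)); R² = sum_j beta_j r_j.
    """
    if not predictors:
        raise EstimationError("no predictors")
    syy = float(sigma.loc[outcome, outcome])
    if syy <= 0:
        raise EstimationError(f"outcome {outcome!r} has zero variance at this level")
    sds = np.sqrt(np.diag(sigma.loc[predictors, predictors].to_numpy()))
    zero_var = [p for p, s in zip(predictors, sds) if not s > 0]
    if zero_var:
        raise EstimationError(f"predictor(s) with zero variance at this level: {zero_var}")

    sxx = sigma.loc[predictors, predictors].to_numpy()
    sxy = sigma.loc[predictors, outcome].to_numpy()
    corr = sxx / np.outer(sds, sds)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < 1e-10 * max(eigvals[-1], 1.0):
        pairs = [
            f"{a} ~ {b}"
            for i, a in enumerate(predictors)
            for j, b in enumerate(predictors)
            if i < j and abs(corr[i, j]) > 1 - 1e-8
        ]
        raise EstimationError(
            "singular predictor covariance; collinear predictors: "
            + (", ".join(pairs) if pairs else str(predictors))
        )
    b = np.linalg.solve(sxx, sxy)
    sy = np.sqrt(syy)
    beta = pd.Series(b * sds / sy, index=predictors, name="beta")
    r = pd.Series(sxy / (sds * sy), index=predictors, name="r")
    r2 = float(beta @ r)
    return beta, r, r2


def pratt_index(beta: pd.Series, r: pd.Series, r2: float) -> pd.Series:
    """PI_j = beta_j * r_j / R²; sums to 1, may be negative (suppression)."""
    if r2 == 0:
        raise EstimationError("Pratt indices undefined: level R² is zero")
    return (beta * r / r2).rename("pratt")


@dataclass
class LevelwiseModelResult:
    """Level-specific regression summary for one meal type."""

    meal: str
    level: str  # "within" | "between"
    outcome: str
    beta: pd.Series
    r: pd.Series
    r2: float
    pratt: pd.Series | None
    pratt_valid: bool
    n_clusters: int
    n_obs: int
    c: float
    dropped: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def predictors(self) -> list[str]:
        return list(self.beta.index)


def expand_covariates(df: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric design columns for the requested covariates.

    Numeric columns pass through; categorical ones are expanded into one dummy
    per non-reference category, named ``<covariate>_<category>`` (y/n flags
    keep the bare covariate name, coded 1 for "y").
    """
    out = {}
    for name in names:
        if name not in df.columns:
            raise ValidationError(f"covariate {name!r} not found")
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            out[name] = col.astype(float)
            continue
        missing = col.isna().to_numpy()
        values = col.astype("string")
        uniq = set(values.dropna().unique())
        if uniq <= {"y", "n"}:
            out[name] = np.where(missing, np.nan, (values == "y").astype(float))
            continue
        categories = _CATEGORY_ORDER.get(name)
        if categories is None:
            ref = REFERENCE_LEVELS.get(name)
            categories = tuple(c for c in sorted(uniq) if c != ref)
        for cat in categories:
            out[f"{name}_{cat}"] = np.where(missing, np.nan, (values == cat).astype(float))
    return pd.DataFrame(out, index=df.index)


def fit_meal_models(
    table: pd.DataFrame,
    participants: pd.DataFrame,
    outcome: str,
    within_covs,
    between_covs,
    meals=DEFAULT_MEALS,
    min_r2: float = 1e-8,
) -> list[LevelwiseModelResult]:
    """Per-meal two-level models: within result from S_PW, between from Sigma_B.

    Expects a preprocessed table (``log_<outcome>`` present, prior intervals
    computed).  Rows missing any covariate (e.g. the first occasion's prior
    interval) are excluded row-wise.  Covariates constant within a meal
    stratum are dropped with a warning; between-level variables whose Sigma_B
    variance was floored at 0 are excluded from the between model.
    """
    log_col = f"log_{outcome}"
    if log_col not in table.columns:
        raise ValidationError(
            f"{log_col} missing: run exclude_zeros_log before fitting meal models"
        )
    merged = table.merge(participants, on="participant_id", how="left", validate="m:1")
    results: list[LevelwiseModelResult] = []

    for meal in meals:
        sub = merged[merged["meal_type"] == meal]
        if sub.empty:
            warnings.warn(f"meal {meal!r} absent from data; skipped", stacklevel=2)
            continue
        xw = expand_covariates(sub, within_covs)
        xb = expand_covariates(sub, between_covs)
        data = pd.concat(
            [sub[["participant_id", log_col]].reset_index(drop=True),
             xw.reset_index(drop=True), xb.reset_index(drop=True)],
            axis=1,
        ).dropna()

        dropped = []
        for colset in (xw, xb):
            for colname in list(colset.columns):
                if data[colname].nunique() <= 1:
                    dropped.append(colname)
        if dropped:
            warnings.warn(
                f"meal {meal!r}: dropping constant covariate(s) {dropped}", stacklevel=2
            )
        wcols = [c for c in xw.columns if c not in dropped]
        bcols = [c for c in xb.columns if c not in dropped]

        z = data[[log_col] + wcols + bcols]
        dec = decompose_two_level(z, data["participant_id"].to_numpy())
        notes = tuple(f"floored between-variance: {v}" for v in dec.floored)

        for level, sigma, preds in (
            ("within", dec.s_pw, wcols),
            ("between", dec.sigma_b, [c for c in bcols if c not in dec.floored]),
        ):
            if level == "between":
                skipped = [c for c in bcols if c in dec.floored]
                if skipped:
                    warnings.warn(
                        f"meal {meal!r}: between-level variance floored at 0 for "
                        f"{skipped}; excluded from the between model",
                        stacklevel=2,
                    )
                if log_col in dec.floored:
                    warnings.warn(
                        f"meal {meal!r}: between-level outcome variance floored at 0; "
                        f"between model skipped",
                        stacklevel=2,
                    )
                    continue
            no_var = [p for p in preds if not sigma.loc[p, p] > 0]
            if no_var:
                warnings.warn(
                    f"meal {meal!r}: no {level}-level variance for {no_var}; "
                    f"excluded from the {level} model",
                    stacklevel=2,
                )
                preds = [p for p in preds if p not in no_var]
            if not preds:
                continue
            beta, r, r2 = level_model(sigma, log_col, preds)
            valid = r2 > min_r2
            pratt = pratt_index(beta, r, r2) if valid else None
            results.append(
                LevelwiseModelResult(
                    meal=meal,
                    level=level,
                    outcome=outcome,
                    beta=beta,
                    r=r,
                    r2=r2,
                    pratt=pratt,
                    pratt_valid=valid,
                    n_clusters=dec.n_clusters,
                    n_obs=dec.n_obs,
                    c=dec.c,
                    dropped=tuple(d for d in dropped),
                    notes=notes,
                )
            )
    return results


def results_to_frame(results: list[LevelwiseModelResult]) -> pd.DataFrame:
    """Tidy table mirroring the published layout: one row per predictor with
    beta, correlation and Pratt index, plus the level R² repeated per row."""
    rows = []
    for res in results:
        for pred in res.predictors:
            rows.append(
                {
                    "outcome": res.outcome,
                    "meal": res.meal,
                    "level": res.level,
                    "predictor": pred,
                    "beta": res.beta[pred],
                    "r": res.r[pred],
                    "pratt": res.pratt[pred] if res.pratt is not None else np.nan,
                    "r2": res.r2,
                    "n_clusters": res.n_clusters,
                    "n_obs": res.n_obs,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "outcome", "meal", "level", "predictor",
            "beta", "r", "pratt", "r2", "n_clusters", "n_obs",
        ],
    )
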