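"""Three-level intercept-only variance components and ICC shares.

The model is a Gaussian nested random-intercept model

    y_ict = mu + u_i + v_ic + e_ict,
    u_i ~ N(0, s2_P),  v_ic ~ N(0, s2_M),  e_ict ~ N(0, s2_e),

with occasions t nested in participant-by-meal cells c nested in participants
i.  The likelihood factorizes into within-cell deviations (variance s2_e) and
cell means whose per-participant covariance is a rank-one update of a
diagonal, so each evaluation is O(number of cells).  The fixed intercept is
profiled out by GLS and the variances are maximized on the log scale, with
boundary estimates projected to exactly 0 by refitting constrained candidates
and keeping the best likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import EstimationError, ValidationError

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class VarianceComponents:
    """Estimated log-scale variances at the three levels plus fit metadata."""

    var_participant: float
    var_mealcell: float
    var_occasion: float
    loglik: float
    n_participants: int
    n_cells: int
    n_obs: int
    converged: bool = True
    truncated: tuple[str, ...] = ()
    method: str = "ml"

    @property
    def total(self) -> float:
        return self.var_participant + self.var_mealcell + self.var_occasion

    def to_record(self) -> dict[str, float]:
        rec = {
            "var_participant": self.var_participant,
            "var_mealcell": self.var_mealcell,
            "var_occasion": self.var_occasion,
            "loglik": self.loglik,
            "n_participants": self.n_participants,
            "n_cells": self.n_cells,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "method": self.method,
        }
        if self.total > 0:
            shares = icc_shares(self)
            rec.update({f"share_{k}": v for k, v in shares.items()})
        return rec


def icc_shares(vc: VarianceComponents) -> dict[str, float]:
    """Proportion of total variance at each level (fractions summing to 1)."""
    total = vc.total
    if total <= 0:
        raise EstimationError("total variance is zero; ICC shares undefined")
    return {
        "participant": vc.var_participant / total,
        "mealcell": vc.var_mealcell / total,
        "occasion": vc.var_occasion / total,
    }


def _prepare(y, participant_ids, cell_ids):
    y = np.asarray(y, dtype=float)
    pid = np.asarray(participant_ids)
    cid = np.asarray(cell_ids)
    if not (len(y) == len(pid) == len(cid)):
        raise ValidationError("y, participant_ids and cell_ids must have equal length")
    if len(y) < 2:
        raise ValidationError("need at least 2 observations")
    if np.isnan(y).any():
        raise ValidationError("y contains missing values")
    cell_codes, cells = pd.factorize(cid)
    part_codes, parts = pd.factorize(pid)
    # nesting: each cell belongs to exactly one participant
    _, first_idx = np.unique(cell_codes, return_index=True)
    cell_part = part_codes[first_idx]
    mismatch = part_codes != cell_part[cell_codes]
    if mismatch.any():
        offender = cells[cell_codes[np.argmax(mismatch)]]
        raise ValidationError(
            f"cell id {offender!r} appears under more than one participant"
        )
    return y, cell_codes, part_codes, cell_part, len(parts), len(cells)


class _Sufficient:
    """Cell-level sufficient statistics for the nested likelihood."""

    def __init__(self, y, cell_codes, cell_part, n_cells, n_parts):
        self.N = len(y)
        self.K = n_cells
        self.G = n_parts
        self.cell_n = np.bincount(cell_codes, minlength=n_cells).astype(float)
        cell_sum = np.bincount(cell_codes, weights=y, minlength=n_cells)
        self.cell_mean = cell_sum / self.cell_n
        self.ssw = float(np.sum(y * y) - np.sum(cell_sum**2 / self.cell_n))
        self.ssw = max(self.ssw, 0.0)
        self.cell_part = cell_part
        self.log_cell_n_sum = float(np.sum(np.log(self.cell_n)))

    def nll(self, vp: float, vm: float, ve: float, reml: bool = False) -> float:
        """Negative profiled log-likelihood (without additive constants)."""
        d = vm + ve / self.cell_n
        inv_d = 1.0 / d
        s_i = np.bincount(self.cell_part, weights=inv_d, minlength=self.G)
        t_i = np.bincount(self.cell_part, weights=self.cell_mean * inv_d, minlength=self.G)
        denom = 1.0 + vp * s_i
        mu = float(np.sum(t_i / denom) / np.sum(s_i / denom))
        mc = self.cell_mean - mu
        a_i = np.bincount(self.cell_part, weights=mc * inv_d, minlength=self.G)
        q_i = np.bincount(self.cell_part, weights=mc * mc * inv_d, minlength=self.G)
        quad = float(np.sum(q_i - vp * a_i**2 / denom))
        logdet = float(np.sum(np.log(d)) + np.sum(np.log(denom)))
        nll = 0.5 * (
            (self.N - self.K) * math.log(ve) + self.ssw / ve + logdet + quad
        )
        if reml:
            nll += 0.5 * math.log(float(np.sum(s_i / denom)))
        return nll

    def loglik(self, vp, vm, ve, reml=False) -> float:
        const = 0.5 * (self.N - (1 if reml else 0)) * _LOG2PI + 0.5 * self.log_cell_n_sum
        return -self.nll(vp, vm, ve, reml=reml) - const


def _starting_values(suff: _Sufficient, vtot: float):
    ve0 = suff.ssw / max(suff.N - suff.K, 1) if suff.N > suff.K else vtot / 3
    ve0 = max(ve0, 1e-4 * vtot)
    cm_var = float(np.var(suff.cell_mean)) if suff.K > 1 else vtot / 3
    vm0 = max(cm_var / 2, 1e-3 * vtot)
    vp0 = max(cm_var / 2, 1e-3 * vtot)
    return vp0, vm0, ve0


def fit_three_level(
    y, participant_ids, cell_ids, method: str = "ml"
) -> VarianceComponents:
    """Maximum-likelihood (or REML) fit of the three-level intercept model.

    Handles unbalanced cells and participants with a single recall; variance
    estimates are constrained to be non-negative, with boundary solutions set
    to exactly 0 (flagged in ``truncated``).
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    reml = method == "reml"
    y, cell_codes, part_codes, cell_part, G, K = _prepare(y, participant_ids, cell_ids)
    N = len(y)
    vtot = float(np.var(y))
    if vtot == 0.0:
        return VarianceComponents(
            0.0, 0.0, 0.0, math.inf, G, K, N, True, ("participant", "mealcell", "occasion"), method
        )
    suff = _Sufficient(y, cell_codes, cell_part, K, G)
    vp0, vm0, ve0 = _starting_values(suff, vtot)
    floor = 1e-12 * vtot

    candidates = []  # (nll, vp, vm, ve, converged, n_fixed)
    for vp_free, vm_free in ((True, True), (False, True), (True, False), (False, False)):
        x0 = []
        if vp_free:
            x0.append(math.log(vp0))
        if vm_free:
            x0.append(math.log(vm0))
        x0.append(math.log(ve0))

        def unpack(x):
            j = 0
            if vp_free:
                vp = math.exp(min(x[j], 50.0))
                j += 1
            else:
                vp = 0.0
            if vm_free:
                vm = math.exp(min(x[j], 50.0))
                j += 1
            else:
                vm = 0.0
            ve = max(math.exp(min(x[j], 50.0)), floor)
            return vp, vm, ve

        def fun(x):
            vp, vm, ve = unpack(x)
            try:
                return suff.nll(vp, vm, ve, reml=reml)
            except (FloatingPointError, ValueError):
                return np.inf

        res = optimize.minimize(
            fun,
            np.asarray(x0),
            method="Nelder-Mead",
            options={
                "xatol": 1e-10,
                "fatol": 1e-12,
                "maxiter": 4000,
                "maxfev": 4000,
            },
        )
        vp, vm, ve = unpack(res.x)
        candidates.append((float(res.fun), vp, vm, ve, bool(res.success), (not vp_free) + (not vm_free)))

    best_nll = min(c[0] for c in candidates)
    # Among near-ties prefer the most constrained fit (projection to boundary).
    best = max(
        (c for c in candidates if c[0] <= best_nll + 1e-8), key=lambda c: c[5]
    )
    nll, vp, vm, ve, converged, _ = best
    truncated = []
    if vp <= floor:
        vp, truncated = 0.0, truncated + ["participant"]
    if vm <= floor:
        vm = 0.0
        truncated.append("mealcell")
    loglik = suff.loglik(vp, vm, ve, reml=reml)
    return VarianceComponents(
        vp, vm, ve, loglik, G, K, N, converged, tuple(truncated), method
    )


def fit_three_level_ml(y, participant_ids, cell_ids) -> VarianceComponents:
    """ML fit (the default estimator used for the ICC decomposition)."""
    return fit_three_level(y, participant_ids, cell_ids, method="ml")


def fit_nested_anova_balanced(y, participant_ids, cell_ids) -> VarianceComponents:
    """Method-of-moments variance components via nested ANOVA.

    Requires a perfectly balanced design: every participant holds M cells and
    every cell n >= 2 observations.  Serves as a closed-form oracle for the
    likelihood fits (for balanced designs the ANOVA estimator coincides with
    REML whenever all estimates are interior).
    """
    y, cell_codes, part_codes, cell_part, G, K = _prepare(y, participant_ids, cell_ids)
    N = len(y)
    cell_n = np.bincount(cell_codes, minlength=K)
    cells_per_part = np.bincount(cell_part, minlength=G)
    if cell_n.min() != cell_n.max() or cells_per_part.min() != cells_per_part.max():
        raise ValidationError(
            "unbalanced design: nested ANOVA requires equal cells per participant "
            "and equal observations per cell; use the ML fit instead"
        )
    n = int(cell_n[0])
    M = int(cells_per_part[0])
    if n < 2:
        raise ValidationError("nested ANOVA needs >= 2 observations per cell")

    cell_mean = np.bincount(cell_codes, weights=y) / n
    part_mean = np.bincount(cell_part, weights=cell_mean) / M
    grand = float(np.mean(y))

    ss_within = float(np.sum((y - cell_mean[cell_codes]) ** 2))
    ss_cell = float(n * np.sum((cell_mean - part_mean[cell_part]) ** 2))
    ss_part = float(n * M * np.sum((part_mean - grand) ** 2))

    ms_within = ss_within / (G * M * (n - 1))
    ms_cell = ss_cell / (G * (M - 1)) if M > 1 else 0.0
    ms_part = ss_part / (G - 1) if G > 1 else 0.0

    ve = ms_within
    vm = (ms_cell - ms_within) / n
    vp = (ms_part - ms_cell) / (n * M)
    truncated = []
    if vm < 0:
        vm = 0.0
        truncated.append("mealcell")
    if vp < 0:
        vp = 0.0
        truncated.append("participant")

    suff = _Sufficient(y, cell_codes, cell_part, K, G)
    loglik = suff.loglik(vp, vm, max(ve, 1e-300)) if ve > 0 else math.inf
    return VarianceComponents(
        vp, vm, ve, loglik, G, K, N, True, tuple(truncated), "anova"
    )
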