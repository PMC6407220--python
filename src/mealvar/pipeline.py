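"""End-to-end orchestration: config in, tables and a result bundle out.

A single config seed fans out deterministically to the simulation and
bootstrap sub-seeds, so identical (config, seed) pairs give byte-identical
result bundles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import bootstrap_ci, make_icc_estimator, make_pratt_estimator
from .config import DEFAULT_MEALS, OUTCOMES, SimulationConfig
from .errors import ConfigurationError, ValidationError
from .io import read_intake_csv, read_participants_csv
from .misreport import add_misreporting, classifiable
from .preprocess import compute_prior_interval, exclude_zeros_log, select_meals
from .twolevel import fit_meal_models, results_to_frame
from .variance import fit_three_level_ml, icc_shares

DEFAULT_WITHIN = ("weekend", "season", "special_day", "prior_interval", "place")
DEFAULT_BETWEEN = ("bmi", "age", "sex", "education", "occupation", "physical_activity", "smoking")


@dataclass
class PipelineResult:
    icc: pd.DataFrame
    meal_models: pd.DataFrame
    bootstrap: pd.DataFrame | None
    sensitivity: pd.DataFrame | None
    participants: pd.DataFrame
    intake: pd.DataFrame
    log: dict = field(default_factory=dict)


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % 2**31)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("pipeline config must be a mapping")
    return dict(config)


def run_pipeline(config) -> PipelineResult:
    """Run simulate/load -> preprocess -> ICC -> meal models -> bootstrap -> sensitivity."""
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    outcomes = tuple(cfg.get("outcomes", OUTCOMES))
    bad = set(outcomes) - set(OUTCOMES)
    if bad:
        raise ConfigurationError(f"unknown outcome(s) {sorted(bad)}")
    meals = tuple(cfg.get("meals", DEFAULT_MEALS))
    within_covs = tuple(cfg.get("within_covariates", DEFAULT_WITHIN))
    between_covs = tuple(cfg.get("between_covariates", DEFAULT_BETWEEN))
    boot_cfg = cfg.get("bootstrap", {}) or {}
    B = int(boot_cfg.get("B", 1000)) if boot_cfg.get("enabled", True) else 0
    boot_icc = bool(boot_cfg.get("icc", True))
    run_sensitivity = bool(cfg.get("sensitivity", True))
    log: dict = {"seed": seed, "versions": _versions(), "warnings": []}

    # ----- data ---------------------------------------------------------------
    if "simulation" in cfg:
        sim = dict(cfg["simulation"] or {})
        sim.setdefault("seed", _derive_seed(seed, 0))
        sim_config = SimulationConfig.from_dict(sim)
        from .simulate import simulate_dataset

        participants, intake = simulate_dataset(sim_config)
        log["simulation_seed"] = sim_config.seed
    elif "inputs" in cfg:
        participants = read_participants_csv(cfg["inputs"]["participants"])
        intake = read_intake_csv(cfg["inputs"]["intake"])
    else:
        raise ConfigurationError("config needs a 'simulation' or 'inputs' section")

    # ----- preprocess ---------------------------------------------------------
    intake = compute_prior_interval(intake, occasion_order=None)
    meal_table = select_meals(intake, meals)
    prepared: dict[str, pd.DataFrame] = {}
    log["n_excluded_zeros"] = {}
    for outcome in outcomes:
        tab, n_excluded = exclude_zeros_log(meal_table, outcome)
        prepared[outcome] = tab
        log["n_excluded_zeros"][outcome] = n_excluded

    # ----- ICC ----------------------------------------------------------------
    icc_rows = []
    for outcome in outcomes:
        tab = prepared[outcome]
        cells = tab["participant_id"].astype(str) + "|" + tab["meal_type"].astype(str)
        vc = fit_three_level_ml(tab[f"log_{outcome}"], tab["participant_id"], cells)
        shares = icc_shares(vc)
        icc_rows.append(
            {
                "outcome": outcome,
                "var_participant": vc.var_participant,
                "var_mealcell": vc.var_mealcell,
                "var_occasion": vc.var_occasion,
                "share_participant_pct": 100 * shares["participant"],
                "share_mealcell_pct": 100 * shares["mealcell"],
                "share_occasion_pct": 100 * shares["occasion"],
                "loglik": vc.loglik,
                "n_obs": vc.n_obs,
                "converged": vc.converged,
            }
        )
    icc_df = pd.DataFrame(icc_rows)

    # ----- meal-stratified two-level models ------------------------------------
    model_frames = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for outcome in outcomes:
            results = fit_meal_models(
                prepared[outcome], participants, outcome, within_covs, between_covs, meals
            )
            model_frames.append(results_to_frame(results))
    log["warnings"].extend(sorted({str(w.message) for w in caught}))
    models_df = pd.concat(model_frames, ignore_index=True) if model_frames else pd.DataFrame()

    # ----- bootstrap ----------------------------------------------------------
    boot_df = None
    if B >= 2:
        boot_frames = []
        for k, outcome in enumerate(outcomes):
            est_pratt = make_pratt_estimator(outcome, within_covs, between_covs, meals)
            if boot_icc:
                est_icc = make_icc_estimator(outcome, meals)

                def est(p, t, _ei=est_icc, _ep=est_pratt):
                    return pd.concat([_ei(p, t), _ep(p, t)])
            else:
                est = est_pratt
            boot_frames.append(
                bootstrap_ci(
                    est, participants, prepared[outcome], B=B, seed=_derive_seed(seed, 1 + k)
                )
            )
        boot_df = pd.concat(boot_frames, ignore_index=True)
        log["bootstrap_B"] = B
        log["bootstrap_n_failed"] = {
            o: int(f["n_failed"].iloc[0]) for o, f in zip(outcomes, boot_frames)
        }

    # ----- misreporting sensitivity -------------------------------------------
    sens_df = None
    if run_sensitivity:
        if "tee_kcal" not in participants.columns or participants["tee_kcal"].notna().sum() == 0:
            warnings.warn("no TEE data: sensitivity analysis skipped")
            log["warnings"].append("no TEE data: sensitivity analysis skipped")
        else:
            augmented = add_misreporting(participants, intake)
            usable = classifiable(augmented)
            log["n_classifiable"] = int(len(usable))
            log["ei_method"] = augmented.attrs.get("ei_method")
            sens_frames = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for outcome in outcomes:
                    tab = prepared[outcome]
                    tab = tab[tab["participant_id"].isin(usable["participant_id"])]
                    results = fit_meal_models(
                        tab,
                        usable,
                        outcome,
                        within_covs,
                        tuple(between_covs) + ("misreporting_class",),
                        meals,
                    )
                    sens_frames.append(results_to_frame(results))
            sens_df = pd.concat(sens_frames, ignore_index=True)

    return PipelineResult(
        icc=icc_df,
        meal_models=models_df,
        bootstrap=boot_df,
        sensitivity=sens_df,
        participants=participants,
        intake=intake,
        log=log,
    )


def write_results(result: PipelineResult, out_dir) -> list[Path]:
    """Write the bundle: tidy CSV per table + full-precision JSON + run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame | None, name: str):
        if df is None:
            return
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    _csv(result.icc, "icc_shares.csv")
    _csv(result.meal_models, "meal_models.csv")
    _csv(result.bootstrap, "bootstrap_ci.csv")
    _csv(result.sensitivity, "meal_models_sensitivity.csv")

    payload = {
        "icc": result.icc.to_dict(orient="records"),
        "meal_models": result.meal_models.to_dict(orient="records"),
        "bootstrap": None
        if result.bootstrap is None
        else result.bootstrap.to_dict(orient="records"),
        "sensitivity": None
        if result.sensitivity is None
        else result.sensitivity.to_dict(orient="records"),
    }
    json_path = out / "results.json"
    json_path.write_text(json.dumps(payload, sort_keys=True, allow_nan=True), encoding="utf-8")
    written.append(json_path)

    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(result.log, sort_keys=True, indent=2), encoding="utf-8")
    written.append(log_path)
    return written


def _versions() -> dict[str, str]:
    import scipy

    return {
        "mealvar": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
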