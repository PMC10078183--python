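"""End-to-end orchestration: simulate -> aggregate -> correct -> fit ->
evaluate -> calibrate.

A declarative config (YAML-able dict) names the synthetic study
conditions, the bias-correction variants to run, the model families,
and the evaluation / field-calibration settings. ``run_pipeline``
executes every stage, writes diffable artifacts (CSV tables, JSON
reports) into a run directory stamped with the config hash and seed,
and returns the in-memory results. All randomness flows from the named
seeds; truth arrays (N, excess flags) are written to a separate
``truth/`` subdirectory and are never read by any fitting stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from biastree import io
from biastree.background_bias import (
    buffer_restricted_background,
    kernel_density_surface,
    random_background,
    raster_bias_surface,
    record_density_surface,
    weighted_background,
)
from biastree.field_calibration import (
    calibrate,
    field_auc,
    national_total,
    select_squares,
    tree_density,
)
from biastree.grid_records import aggregate_to_counts, overdispersion_ratio
from biastree.model_evaluation import (
    aicc,
    auc,
    correlate,
    kfold_cv,
    rmsle,
    threshold_to_pa,
)
from biastree.occurrence_filtering import (
    cluster_filter,
    systematic_sample,
    weighted_distance_sample,
)
from biastree.presence_background_sdm import (
    DesignSpec,
    covariates_at_points,
    fit_presence_background,
    predict_suitability,
    select_model_by_aicc,
)
from biastree.synthetic_landscape import (
    LandscapeConfig,
    TruthConfig,
    generate_landscape,
    place_points,
    simulate_field_survey,
    simulate_recorders,
    simulate_sampling,
    simulate_true_abundance,
)
from biastree.zi_regression import fit_zi, predict_zi, vuong_test

log = logging.getLogger("biastree")

# Default study conditions: a 50x50 grid of 1-km cells, three smooth
# numeric covariates plus one 3-level land class, strongly overdispersed
# true abundance and a covariate-driven non-sampling process censoring
# roughly 40% of cells.
DEFAULT_CONFIG: dict = {
    "seed": 1,
    "synthetic": {
        "n_rows": 50,
        "n_cols": 50,
        "cell_size": 1000.0,
        "n_numeric_covariates": 3,
        "categorical_levels": {"landclass": 3},
        "covariate_correlation_length": 5000.0,
        "truth": {
            "beta_count": [0.4, 0.8, -0.5, 0.3, 0.3, -0.3],
            "theta": 0.5,
            "gamma_zero": [-0.4, 0.8, 0.0, -0.5, 0.3, 0.0],
            "detection_prob": 1.0,
        },
        "n_recorders": 15,
        "recorder_activity_decay": 10_000.0,
    },
    "bias_methods": [
        {"name": "none"},
        {"name": "systematic", "resolution": 2000.0},
        {"name": "cluster", "link_distance": 1000.0},
        {"name": "weighted_distance", "n_keep": 500},
        {"name": "buffer", "radius": 5000.0},
        {"name": "bias_file", "source": "recorder_density", "bandwidth": 5000.0},
        {"name": "bias_file", "source": "record_density"},
        {"name": "bias_file", "source": "raster", "covariate": "cov1", "direction": "ascending"},
    ],
    "models": {
        "zi_families": ["poisson", "negbin"],
        "n_background": 2000,
        "lambda_grid": [0.0, 0.1, 1.0],
        "features": "linear",
    },
    "evaluation": {"k": 10},
    "calibration": {
        "n_random": 20,
        "n_per_stratum": 5,
        "metric": "density",
        "completion_prob": 0.58,
        "p_inaccessible": 0.044,
        "coverage_beta": [2.2, 1.5],
        "min_coverage": 0.05,
    },
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


def config_hash(config: dict) -> str:
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def simulate_stage(config: dict):
    """Generate landscape, truth, observations, records and recorders."""
    syn = config["synthetic"]
    seed = int(config["seed"])
    lcfg = LandscapeConfig(
        n_rows=syn["n_rows"],
        n_cols=syn["n_cols"],
        cell_size=syn["cell_size"],
        n_numeric_covariates=syn["n_numeric_covariates"],
        categorical_levels=dict(syn["categorical_levels"]),
        covariate_correlation_length=syn["covariate_correlation_length"],
        seed=seed,
    )
    landscape = generate_landscape(lcfg)
    truth = TruthConfig(
        beta_count=tuple(syn["truth"]["beta_count"]),
        theta=syn["truth"]["theta"],
        gamma_zero=tuple(syn["truth"]["gamma_zero"]),
        detection_prob=syn["truth"]["detection_prob"],
        seed=seed + 1,
    )
    N = simulate_true_abundance(landscape, truth)
    Y, excess = simulate_sampling(landscape, N, truth)
    records = place_points(landscape, Y, seed=seed + 2)
    homes, records = simulate_recorders(
        landscape,
        records,
        n_recorders=syn["n_recorders"],
        activity_decay=syn["recorder_activity_decay"],
        seed=seed + 3,
    )
    return landscape, truth, N, Y, excess, records, homes


def build_presences_background(
    method: dict, records, landscape, Y, homes, n_background: int, seed: int
):
    """One bias-correction variant -> (label, presences, background)."""
    name = method["name"]
    if name == "none":
        pres = records
        bg = random_background(landscape, n_background, seed)
        label = "none"
    elif name == "systematic":
        res = float(method["resolution"])
        pres = systematic_sample(records, res, seed)
        bg = random_background(landscape, n_background, seed)
        label = f"systematic_{int(res / 1000)}km"
    elif name == "cluster":
        pres = cluster_filter(records, float(method["link_distance"]), seed)
        bg = random_background(landscape, n_background, seed)
        label = "cluster"
    elif name == "weighted_distance":
        n_keep = min(int(method["n_keep"]), len(records))
        pres = weighted_distance_sample(records, n_keep, seed)
        bg = random_background(landscape, n_background, seed)
        label = "weighted_distance"
    elif name == "buffer":
        pres = records
        bg = buffer_restricted_background(
            records, float(method["radius"]), landscape, n_background, seed
        )
        label = f"buffer_{int(float(method['radius']) / 1000)}km"
    elif name == "bias_file":
        pres = records
        source = method["source"]
        if source == "recorder_density":
            surface = kernel_density_surface(homes, float(method["bandwidth"]), landscape)
        elif source == "record_density":
            surface = record_density_surface(Y)
        elif source == "raster":
            vals = landscape.cells[method["covariate"]].to_numpy(dtype=float)
            surface = raster_bias_surface(vals, method.get("direction", "ascending"))
        else:
            raise ValueError(f"unknown bias source {source!r}")
        bg = weighted_background(surface, landscape, n_background, seed)
        label = f"bias_{source}"
    else:
        raise ValueError(f"unknown bias method {name!r}")
    return label, pres, bg


def _fit_pb_with_tuning(points, labels, spec, lambda_grid):
    """Fit one penalized PB model per lambda and keep the AICc winner."""
    pres = points[labels == 1]
    bg = points[labels == 0]
    fits = []
    for lam in lambda_grid:
        try:
            fits.append(fit_presence_background(pres, bg, spec, lam=float(lam)))
        except RuntimeError:
            continue
    if not fits:
        raise RuntimeError("no presence-background candidate converged")
    return select_model_by_aicc(fits)


def evaluate_pb_model(
    label, presences, background, landscape, k, seed, lambda_grid, features
):
    """Fit + AICc-tune a PB model; cross-validate point-level AUC."""
    spec = DesignSpec(
        numeric=tuple(landscape.numeric_names),
        categorical=tuple(landscape.categorical_names),
        features=features,
    )
    pres_cov = covariates_at_points(landscape, presences[["x", "y"]])
    bg_cov = covariates_at_points(landscape, background[["x", "y"]])
    best = _fit_pb_with_tuning(
        pd.concat([pres_cov, bg_cov], ignore_index=True),
        np.concatenate([np.ones(len(pres_cov)), np.zeros(len(bg_cov))]),
        spec,
        lambda_grid,
    )
    points = pd.concat([pres_cov, bg_cov], ignore_index=True)
    points["label"] = np.concatenate([np.ones(len(pres_cov)), np.zeros(len(bg_cov))])

    def fit_fn(train):
        return _fit_pb_with_tuning(
            train, train["label"].to_numpy(), spec, lambda_grid
        )

    def predict_fn(fit, test):
        return predict_suitability(fit, test)

    cv = kfold_cv(points, k=k, seed=seed, fit_fn=fit_fn, predict_fn=predict_fn)
    ok = ~np.isnan(cv.predictions)
    auc_test = auc(points["label"].to_numpy()[ok], cv.predictions[ok])
    train_scores = predict_suitability(best, points)
    auc_train = auc(points["label"].to_numpy(), train_scores)
    cell_pred = predict_suitability(best, landscape.cells)
    a = aicc(best.loglik, best.k, best.n)
    return {
        "model": label,
        "kind": "suitability",
        "fit": best,
        "aicc": a,
        "auc_train": auc_train,
        "auc_test": auc_test,
        "cell_predictions": cell_pred,
    }


def evaluate_zi_models(landscape, Y, families, k, seed):
    """Fit ZI families on the cell counts; CV the three prediction types."""
    X, names = landscape.design_matrix()
    cells = landscape.cells.copy()
    cells["Y"] = Y
    results = {}
    fits = {}
    for family in families:
        fit = fit_zi(X, X, Y, family=family, names_count=names, names_zero=names)
        fits[family] = fit

        idx_frame = pd.DataFrame({"i": np.arange(len(Y))})

        def fit_fn(train, family=family):
            rows = train["i"].to_numpy()
            return fit_zi(X[rows], X[rows], Y[rows], family=family)

        def predict_fn(f, test):
            rows = test["i"].to_numpy()
            return predict_zi(f, (X[rows], X[rows]), type="whole")

        cv = kfold_cv(idx_frame, k=k, seed=seed, fit_fn=fit_fn, predict_fn=predict_fn)
        preds = predict_zi(fit, (X, X), type="all")
        ok = ~np.isnan(cv.predictions)
        _, rs = correlate(cv.predictions[ok], Y[ok])
        pa, thr = threshold_to_pa(cv.predictions[ok], method="mean")
        auc_test = auc((Y[ok] > 0).astype(int), pa)
        train_pa, _ = threshold_to_pa(preds.whole, method="mean")
        auc_train = auc((Y > 0).astype(int), train_pa)
        for kind in ("count", "whole"):
            results[f"zi_{family}_{kind}"] = {
                "model": f"zi_{family}_{kind}",
                "kind": "abundance",
                "fit": fit,
                "aicc": aicc(fit.loglik, fit.k, fit.n),
                "auc_train": auc_train,
                "auc_test": auc_test,
                "cv_spearman": rs,
                "rmsle": rmsle(np.maximum(cv.predictions[ok], 0), Y[ok]),
                "cell_predictions": getattr(preds, kind),
            }
    return results, fits


def field_stage(config, landscape, N, Y, zero_pred, model_rows, seed):
    """Select squares, simulate surveys, calibrate each model, total up."""
    cal = config["calibration"]
    cells = landscape.cells.copy()
    cells["Y"] = Y
    squares = select_squares(
        cells,
        zero_pred,
        n_random=cal["n_random"],
        n_per_stratum=cal["n_per_stratum"],
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    # accessibility rejection-and-replacement
    p_bad = float(cal.get("p_inaccessible", 0.0))
    if p_bad > 0:
        taken = set(squares["cell_id"].tolist())
        for i in squares.index:
            if rng.random() < p_bad:
                stratum = squares.loc[i, "stratum"]
                if stratum == "random":
                    pool = cells.loc[~cells["cell_id"].isin(taken), "cell_id"].to_numpy()
                else:
                    pool = np.array(
                        [c for c in cells["cell_id"] if c not in taken], dtype=int
                    )
                if pool.size:
                    new = int(rng.choice(pool))
                    taken.discard(int(squares.loc[i, "cell_id"]))
                    taken.add(new)
                    squares.loc[i, "cell_id"] = new
    completed = rng.random(len(squares)) < float(cal.get("completion_prob", 1.0))
    if completed.sum() < 3:
        completed[:] = True
    a_, b_ = cal["coverage_beta"]
    min_cov = float(cal.get("min_coverage", 0.05))

    def coverage(rng_, n):
        return np.clip(rng_.beta(a_, b_, size=n), min_cov, 1.0)

    sq_ids = squares["cell_id"].to_numpy()
    survey = simulate_field_survey(
        sq_ids,
        N[sq_ids],
        coverage,
        detection_prob=1.0,
        seed=seed + 2,
        cell_area=landscape.cell_size**2,
    )
    survey["stratum"] = squares["stratum"].to_numpy()
    survey["completed"] = completed
    done = survey[survey["completed"]]
    cell_area = landscape.cell_size**2
    density = tree_density(
        done["observed_count"], done["coverage_fraction"], cell_area
    )
    pa_field = (done["observed_count"].to_numpy() > 0).astype(int)

    out_rows = []
    for row in model_rows:
        preds = row["cell_predictions"]
        p_done = preds[done["cell_id"].to_numpy()]
        p_all_squares = preds[sq_ids]
        entry = dict(row)
        entry.pop("cell_predictions")
        entry.pop("fit", None)
        try:
            r, rs = correlate(p_done, density)
        except ValueError:
            r, rs = np.nan, np.nan
        entry["field_r"], entry["field_rs"] = r, rs
        try:
            entry["field_auc"] = field_auc(
                p_done,
                pa_field,
                threshold_reference=p_all_squares,
                kind="abundance" if row["kind"] == "abundance" else "suitability",
            )
        except ValueError:
            entry["field_auc"] = np.nan
        try:
            cal_fit = calibrate(p_done, density, metric="density")
            total = national_total(cal_fit, preds, cell_area=cell_area)
            entry["T_density"] = total.total
            abund = done["observed_count"].to_numpy()
            cal_ab = calibrate(p_done, abund, metric="abundance")
            entry["T_abundance"] = national_total(cal_ab, preds).total
        except ValueError:
            entry["T_density"] = np.nan
            entry["T_abundance"] = np.nan
        out_rows.append(entry)
    return survey, pd.DataFrame(out_rows)


def closed_loop_total(seed: int, family: str = "negbin", config: dict | None = None) -> dict:
    """One full abundance closed loop: simulate, fit, survey, calibrate.

    Generates a landscape under the default study conditions (a 50x50
    grid unless overridden), fits a ZI model to the observed counts,
    selects survey squares (random tranche + four strata), simulates
    partial-coverage surveys, calibrates the count prediction against
    effort-adjusted density over completed squares, and sums to the
    landscape total T. Returns the total alongside the true abundance
    sum; used for replicate-based recovery analyses.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if config:
        _deep_update(cfg, config)
    cfg["seed"] = int(seed)
    landscape, truth, N, Y, excess, records, homes = simulate_stage(cfg)
    X, names = landscape.design_matrix()
    fit = fit_zi(X, X, Y, family=family, names_count=names, names_zero=names)
    zero_pred = predict_zi(fit, (X, X), type="zero")
    count_pred = predict_zi(fit, (X, X), type="count")
    row = {
        "model": f"zi_{family}_count",
        "kind": "abundance",
        "cell_predictions": count_pred,
    }
    survey, table = field_stage(cfg, landscape, N, Y, zero_pred, [row], seed + 13)
    return {
        "T": float(table["T_density"].iloc[0]),
        "T_abundance": float(table["T_abundance"].iloc[0]),
        "sum_N": int(N.sum()),
        "sum_Y": int(Y.sum()),
        "field_rs": float(table["field_rs"].iloc[0]),
        "vuong_fit": fit,
    }


def run_pipeline(config: dict | None = None, out_dir=None) -> dict:
    """Run the full synthetic study; optionally write artifacts.

    Returns a dict with the landscape, truth arrays, per-model
    comparison table, ZI fits and the Vuong comparison.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if config:
        _deep_update(cfg, config)
    seed = int(cfg["seed"])
    stamp = config_hash(cfg)
    log.info("pipeline start (config %s, seed %d)", stamp, seed)

    landscape, truth, N, Y_sim, excess, records, homes = simulate_stage(cfg)
    Y = aggregate_to_counts(records, landscape)
    if not np.array_equal(Y, Y_sim):
        raise AssertionError("aggregation does not reproduce simulated counts")
    log.info(
        "simulated %d records in %d/%d cells (var:mean %.1f)",
        len(records),
        int((Y > 0).sum()),
        landscape.n_cells,
        overdispersion_ratio(Y),
    )

    models_cfg = cfg["models"]
    k = int(cfg["evaluation"]["k"])
    rows = []
    for method in cfg["bias_methods"]:
        label, pres, bg = build_presences_background(
            method, records, landscape, Y, homes,
            int(models_cfg["n_background"]), seed + 10,
        )
        log.info("PB model %s: %d presences, %d background", label, len(pres), len(bg))
        rows.append(
            evaluate_pb_model(
                label, pres, bg, landscape, k, seed + 11,
                models_cfg["lambda_grid"], models_cfg["features"],
            )
        )

    zi_rows, zi_fits = evaluate_zi_models(
        landscape, Y, models_cfg["zi_families"], k, seed + 12
    )
    rows.extend(zi_rows.values())

    vuong = None
    if {"poisson", "negbin"} <= set(zi_fits):
        vuong = vuong_test(zi_fits["negbin"], zi_fits["poisson"], correction="aicc")
        log.info("Vuong AICc NB vs Poisson: Z = %.2f", -vuong.z)

    zero_fit = zi_fits.get("negbin") or next(iter(zi_fits.values()))
    zero_pred = predict_zi(zero_fit, landscape, type="zero")
    survey, comparison = field_stage(
        cfg, landscape, N, Y, zero_pred, rows, seed + 13
    )

    results = {
        "config": cfg,
        "config_hash": stamp,
        "landscape": landscape,
        "truth": truth,
        "N": N,
        "Y": Y,
        "excess": excess,
        "records": records,
        "homes": homes,
        "zi_fits": zi_fits,
        "vuong": vuong,
        "survey": survey,
        "comparison": comparison,
        "model_rows": rows,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        io.write_records_csv(records, out / "records.csv")
        io.write_cells_csv(landscape, out / "cells.csv", Y=Y)
        pd.DataFrame(
            {"cell_id": landscape.cells["cell_id"], "N": N, "excess": excess}
        ).to_csv(out / "truth" / "truth.csv", index=False)
        homes.to_csv(out / "recorders.csv", index=False)
        survey.to_csv(out / "survey.csv", index=False)
        comparison.to_csv(out / "comparison.csv", index=False)
        meta = {"config_hash": stamp, "seed": seed, "config": cfg}
        if vuong is not None:
            meta["vuong_nb_vs_poisson_z"] = -vuong.z
        with open(out / "run_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=float)
        log.info("artifacts written to %s", out)
    return results
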