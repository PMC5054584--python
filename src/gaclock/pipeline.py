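"""End-to-end driver chaining the full analysis on one dataset.

Stage order is fixed: detection-p mask -> probe missingness filter ->
sample missingness filter -> probe intersection across datasets -> gold
standard -> BMIQ calibration -> kNN imputation -> clock training ->
prediction -> downstream analyses.  Every stage writes its artifacts into
the run directory and the run ends with a deterministic ``summary.json``
(per-stage probe/sample counts, selected lambda, clock size, accuracy).

All randomness flows from one top-level seed, expanded per stage with
numpy's seed-sequence spawning.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .acceleration import assoc_birthweight, build_acceleration_table
from .bmiq import build_gold_standard, calibrate_matrix
from .cellcomp import estimate_proportions, select_discriminating_probes
from .clock import GestationalAgeClock, TrainingConfig, predict_ga
from .datamodel import BetaMatrix, ValidationError
from .ewas import compare_adjustment, ewas_ga, n_significant
from .impute import knn_impute
from .qc import filter_missingness, intersect_probes, mask_by_detection
from .synth import SimulationConfig, simulate_dataset

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

log = logging.getLogger("gaclock.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},              # SimulationConfig overrides
    "test_fraction": 1 / 3,
    "detection_threshold": 0.001,
    "probe_max_missing": 0.05,
    "sample_max_missing": 0.05,
    "skip_normalize": False,
    "knn_k": 10,
    "alpha": 0.5,
    "n_folds": 10,
    "n_lambda": 100,
    "run_ewas": True,
    "run_cellcomp": True,
    "run_acceleration": True,
}


def _stage(name: str, t0: float, **kv) -> None:
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.time() - t0, pairs)


def run_pipeline(config: dict | None = None, out_dir: str | Path = "gaclock_run") -> dict:
    """Run the whole chain on a synthetic dataset; returns the summary dict.

    ``config`` overrides :data:`DEFAULT_CONFIG` key by key; the
    ``simulate`` sub-dict overrides :class:`SimulationConfig` fields.  On
    error the run halts naming the failing stage; artifacts written so far
    are preserved in ``out_dir``.
    """
    progress: dict = {"stages": {}}
    try:
        return _run_pipeline(config, out_dir, progress)
    except Exception as exc:
        done = list(progress["stages"])
        last = done[-1] if done else "(none)"
        raise RuntimeError(
            f"pipeline failed after stage {last!r} (artifacts preserved in "
            f"{out_dir}): {exc}"
        ) from exc


def _run_pipeline(config: dict | None, out_dir: str | Path, progress: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"stages": progress["stages"],
                     "config": {k: v for k, v in cfg.items() if k != "simulate"}}

    seeds = np.random.SeedSequence(cfg["seed"]).spawn(4)
    sim_seed = int(seeds[0].generate_state(1)[0] % (2**31 - 1))
    split_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))
    clock_seed = int(seeds[2].generate_state(1)[0] % (2**31 - 1))

    # ------------------------------------------------------------------ simulate
    sim_cfg = SimulationConfig(**{"seed": sim_seed, **cfg["simulate"]})
    beta, detp, sheet, truth = simulate_dataset(sim_cfg)
    io.write_beta_matrix(beta, out / "beta_raw.tsv")
    io.write_sample_sheet(sheet, out / "sample_sheet.csv")
    summary["stages"]["simulate"] = {
        "n_probes": beta.shape[0], "n_samples": beta.shape[1],
        "n_causal": int(len(truth.causal_slopes)),
    }
    _stage("simulate", t0, probes=beta.shape[0], samples=beta.shape[1])

    # train/test split
    rng = np.random.default_rng(split_seed)
    n = beta.shape[1]
    test_idx = np.sort(rng.choice(n, size=int(round(cfg["test_fraction"] * n)), replace=False))
    test_ids = beta.sample_ids[test_idx]
    train_ids = beta.sample_ids[~beta.sample_ids.isin(test_ids)]
    groups = {"train": train_ids, "test": test_ids}

    # ------------------------------------------------------------------ qc
    filtered = {}
    for name, ids in groups.items():
        b = BetaMatrix(beta.data[list(ids)])
        d = type(detp)(detp.data[list(ids)])
        masked, n_masked = mask_by_detection(b, d, cfg["detection_threshold"])
        fb, report = filter_missingness(
            masked, cfg["probe_max_missing"], cfg["sample_max_missing"]
        )
        filtered[name] = fb
        summary["stages"][f"qc_{name}"] = {
            "n_cells_masked": n_masked,
            "probes_retained": report.probes_retained,
            "samples_retained": report.samples_retained,
            "probes_dropped": int(len(report.probes_dropped)),
            "samples_dropped": int(len(report.samples_dropped)),
        }
        _stage(f"qc_{name}", t0, masked=n_masked, probes=report.probes_retained)

    train_b, test_b = intersect_probes([filtered["train"], filtered["test"]])
    filtered_train_common, filtered_test_common = train_b, test_b
    summary["stages"]["intersect"] = {"common_probes": train_b.shape[0]}

    # ------------------------------------------------------------------ normalize
    if cfg["skip_normalize"]:
        summary["stages"]["normalize"] = {"skipped": True}
        _stage("normalize", t0, skipped=True)
        gold = None
    else:
        gold = build_gold_standard([train_b])
        gold.save(out / "gold_standard.tsv", out / "gold_standard_fit.json")
        train_b = calibrate_matrix(train_b, gold)
        test_b = calibrate_matrix(test_b, gold)
        summary["stages"]["normalize"] = {
            "skipped": False,
            "gold_n_probes": int(len(gold.values)),
            "gold_mixture_converged": bool(gold.fit.converged),
        }
        _stage("normalize", t0, gold_probes=len(gold.values))

    # ------------------------------------------------------------------ impute
    # EWAS and cell deconvolution run on the uncalibrated (QC'd, imputed)
    # betas: quantile calibration to the training reference imposes the
    # reference marginal on every sample, which distorts per-probe tests
    # and the raw-scale reference profiles
    train_raw = knn_impute(filtered_train_common, k=cfg["knn_k"])
    test_raw = knn_impute(filtered_test_common, k=cfg["knn_k"])
    train_b = train_raw if cfg["skip_normalize"] else knn_impute(train_b, k=cfg["knn_k"])
    test_b = test_raw if cfg["skip_normalize"] else knn_impute(test_b, k=cfg["knn_k"])
    io.write_beta_matrix(train_b, out / "beta_train.tsv")
    io.write_beta_matrix(test_b, out / "beta_test.tsv")
    summary["stages"]["impute"] = {"k": cfg["knn_k"]}
    _stage("impute", t0)

    # ------------------------------------------------------------------ clock
    tcfg = TrainingConfig(alpha=cfg["alpha"], n_folds=cfg["n_folds"],
                          n_lambda=cfg["n_lambda"], seed=clock_seed)
    clock = GestationalAgeClock.from_beta(train_b, sheet, config=tcfg)
    results = clock.fit()
    model = results.to_clock_model()
    io.write_clock_model(model, out / "clock_model.csv")
    tr_r, tr_med, tr_mean, tr_sd = results.training_accuracy()
    summary["stages"]["train"] = {
        "lambda": results.lambda_,
        "n_selected_cpgs": results.n_selected,
        "training_r": round(tr_r, 6),
        "training_median_abs_err": round(tr_med, 6),
    }
    _stage("train", t0, selected=results.n_selected, r=f"{tr_r:.4f}")

    pred = predict_ga(test_b, model, sheet=sheet, gold=gold)
    pred_out = pred.table.copy()
    pred_out["residual"] = pred_out["dnam_ga_weeks"] - pred_out["effective_ga_weeks"]
    pred_out.to_csv(out / "predictions.tsv", sep="\t", index=False)
    summary["stages"]["predict"] = {
        "n_samples": int(len(pred.table)),
        "holdout_r": round(pred.r, 6),
        "holdout_median_abs_err": round(pred.median_abs_err, 6),
        "holdout_mean_abs_err": round(pred.mean_abs_err, 6),
    }
    _stage("predict", t0, r=f"{pred.r:.4f}", med=f"{pred.median_abs_err:.3f}")

    # ------------------------------------------------------------------ cell composition
    proportions = None
    if cfg["run_cellcomp"]:
        profiles = select_discriminating_probes(truth.reference_profiles, n_per_type=50)
        usable = profiles.data.loc[profiles.probe_ids.isin(test_raw.probe_ids)]
        proportions = estimate_proportions(test_raw, type(profiles)(usable))
        proportions.to_csv(out / "cell_proportions.tsv", sep="\t")
        true_p = truth.cell_proportions.loc[proportions.index]
        rmse = float(np.sqrt(np.mean((proportions.to_numpy() - true_p.to_numpy()) ** 2)))
        summary["stages"]["cellcomp"] = {
            "n_reference_probes": int(len(usable)),
            "proportion_rmse_vs_truth": round(rmse, 6),
        }
        _stage("cellcomp", t0, rmse=f"{rmse:.4f}")

    # ------------------------------------------------------------------ acceleration
    if cfg["run_acceleration"]:
        table = build_acceleration_table(pred.table, sheet, cell_proportions=proportions)
        table.to_csv(out / "acceleration.tsv", sep="\t", index=False)
        bw = assoc_birthweight(table, outcome="grams")
        bwp = assoc_birthweight(table, outcome="percentile")
        summary["stages"]["acceleration"] = {
            "birthweight_slope": round(bw.estimate, 6),
            "birthweight_p": round(bw.p, 6),
            "percentile_slope": round(bwp.estimate, 6),
            "percentile_p": round(bwp.p, 6),
        }
        _stage("acceleration", t0, bw_p=f"{bw.p:.3g}")

    # ------------------------------------------------------------------ ewas
    if cfg["run_ewas"]:
        res_u = ewas_ga(train_raw, sheet, adjust_cells=False)
        res_u.to_csv(out / "ewas.tsv", sep="\t")
        entry = {
            "n_probes": int(len(res_u)),
            "n_nominal_significant": n_significant(res_u),
        }
        if cfg["run_cellcomp"]:
            profiles = select_discriminating_probes(truth.reference_profiles, n_per_type=50)
            usable = profiles.data.loc[profiles.probe_ids.isin(train_raw.probe_ids)]
            train_props = estimate_proportions(train_raw, type(profiles)(usable))
            res_a = ewas_ga(train_raw, sheet, adjust_cells=True, proportions=train_props)
            _, t_corr = compare_adjustment(res_u, res_a)
            entry["t_correlation_unadj_vs_adj"] = round(t_corr, 6)
        summary["stages"]["ewas"] = entry
        _stage("ewas", t0, significant=entry["n_nominal_significant"])

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _stage("done", t0)
    return summary
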