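"""End-to-end pipeline: simulate -> exclude -> fit -> compare -> report.

Config is a plain mapping (or YAML file) with the keys shown in
:data:`DEFAULT_CONFIG`; every stage logs and is deterministic per seed, so
re-running the same config reproduces the artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assess import absolute_fit, coherence_level_change
from .compare import compare
from .fitting import WienerLearningModel, exclude_trials, fit_mle
from .models import ModelSpec
from .simulate import (PopulationConfig, generate_design, sample_ground_truth,
                       simulate_trials, write_trials_csv)

__all__ = ["DEFAULT_CONFIG", "run_pipeline", "load_config"]

log = logging.getLogger("driftlearn")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "driftlearn_run",
    "n_subjects": 4,
    "n_days": 4,
    "trials_per_day": 140,          # 7 coherence levels x 20
    "per_level": 20,
    "generating_model": "D",
    "population": {},               # PopulationConfig field overrides
    "models": ["A", "D"],
    "backend": "mle",
    "n_restarts": 3,
    "input_csv": None,              # fit an existing table instead of simulating
    "absolute_fit_block": 25,
}


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return {**DEFAULT_CONFIG, **cfg}


def run_pipeline(config: dict | str | Path) -> Path:
    """Run the full analysis pipeline; returns the artifacts directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    seed = int(cfg["seed"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    log.addHandler(fh)
    try:
        return _run(cfg, seed, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(cfg, seed, out):
    stage = "simulate"
    try:
        if cfg["input_csv"]:
            from .simulate import read_trials_csv
            table = read_trials_csv(cfg["input_csv"])
            log.info("loaded %d trials from %s", len(table), cfg["input_csv"])
        else:
            spec_gen = ModelSpec(cfg["generating_model"], n_days=cfg["n_days"],
                                 trials_per_day=cfg["trials_per_day"])
            design = generate_design(cfg["n_subjects"], cfg["n_days"],
                                     cfg["trials_per_day"], per_level=cfg["per_level"],
                                     seed=seed)
            pop = PopulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in (cfg.get("population") or {}).items()})
            truth = sample_ground_truth(spec_gen, cfg["n_subjects"], seed=seed + 1,
                                        config=pop)
            table = simulate_trials(design, truth, spec_gen, seed=seed + 2)
            write_trials_csv(table, out / "trials.csv")
            log.info("simulated %d trials under model %s", len(table),
                     cfg["generating_model"])

        stage = "exclude"
        filtered, report = exclude_trials(table)
        report.to_csv(out / "exclusion_report.csv", index=False)
        log.info("retained %d / %d trials", len(filtered), len(table))

        stage = "fit"
        fits = []
        for mid in cfg["models"]:
            model = WienerLearningModel(filtered, mid, exclude=False,
                                        trials_per_day=cfg["trials_per_day"])
            res = model.fit(method=cfg["backend"], seed=seed,
                            n_restarts=cfg["n_restarts"])
            fits.append(res)
            res.natural_estimates().to_csv(out / f"estimates_{mid}.csv")
            np.savetxt(out / f"pointwise_loglik_{mid}.csv",
                       res.pointwise.T, delimiter=",")
            log.info("fit model %s: loglik %.2f", mid, res.llf)

        stage = "compare"
        comp = compare(fits)
        comp.table.to_csv(out / "comparison.csv", index=False)

        stage = "report"
        best = fits[int(np.argmin([f.bic if f.backend == "mle" else 0 for f in fits]))]
        r_acc, r_rt, cells = absolute_fit(filtered, best,
                                          block=cfg["absolute_fit_block"])
        cells.to_csv(out / "block_summaries.csv", index=False)
        changes = coherence_level_change(filtered)
        changes.to_csv(out / "coherence_level_change.csv", index=False)
        summary = {
            "seed": seed,
            "n_trials_retained": int(len(filtered)),
            "models": list(cfg["models"]),
            "criterion": comp.criterion,
            "best_model": str(comp.table.iloc[0]["model"]),
            "absolute_fit_r_accuracy": None if np.isnan(r_acc) else round(r_acc, 4),
            "absolute_fit_r_rt": None if np.isnan(r_rt) else round(r_rt, 4),
        }
        with open(out / "report.json", "w", encoding="utf-8") as fhj:
            json.dump(summary, fhj, indent=2, sort_keys=True)
        with open(out / "report.txt", "w", encoding="utf-8") as fht:
            fht.write(str(comp) + "\n\n")
            for f in fits:
                fht.write(f.summary() + "\n\n")
            fht.write(f"absolute fit: r_accuracy={r_acc:.3f} r_rt={r_rt:.3f}\n")
        log.info("pipeline done: best model %s", summary["best_model"])
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
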