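"""End-to-end pipeline: simulate -> covariates -> DSI -> fits -> prediction.

A :class:`PipelineConfig` (YAML-friendly) drives the stages in dependency
order; every run writes a manifest listing each output file with its row
count and a hash of the configuration, and a log with the seed and
per-stage timing. All randomness derives from the single configured seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import sociality
from .hazard import AssociationSpec
from .joint import MCMCConfig, build_joint_data, diagnostics, fit_joint
from .longitudinal import fit_lmm, r2_nakagawa
from .prediction import (conditional_survival, median_survival_age,
                         percentile_trajectory)
from .simulate import SimConfig, simulate_all, write_csvs

log = logging.getLogger("gcjoint.pipeline")

ALL_STAGES = ("simulate", "covariates", "dsi", "fit_longitudinal",
              "fit_joint", "predict", "report")


@dataclass
class PipelineConfig:
    outdir: str = "gcjoint_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=lambda: {"chains": 2, "iterations": 1000,
                                                "warmup": 500})
    assoc_mode: str = "auc"
    assoc_alpha: float = 0.115
    predict: dict = field(default_factory=lambda: {"percentiles": [90, 10],
                                                   "t0": 14.0, "grid_max": 28.0,
                                                   "grid_step": 0.25})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _demo_sim_config(cfg: PipelineConfig) -> SimConfig:
    kw = dict(cfg.sim)
    kw.setdefault("seed", cfg.seed)
    assoc = AssociationSpec(cfg.assoc_mode, cfg.assoc_alpha)
    kw["assoc"] = assoc
    return SimConfig(**kw)


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(config.outdir, "pipeline.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("gcjoint")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest = {"config_hash": config.hash(), "seed": config.seed, "files": {},
                "timing_s": {}}
    log.info("run: seed=%d hash=%s stages=%s", config.seed, config.hash(),
             list(config.stages))

    def record(files: dict):
        for name, (path, rows) in files.items():
            manifest["files"][name] = {"path": path, "rows": rows}

    def save_df(name, df):
        path = os.path.join(config.outdir, name)
        df.to_csv(path, index=False)
        manifest["files"][name] = {"path": path, "rows": len(df)}
        return path

    try:
        sim = None
        t0 = time.perf_counter()
        if "simulate" in config.stages:
            sim = simulate_all(_demo_sim_config(config),
                               behavior="dsi" in config.stages)
            record(write_csvs(sim, config.outdir))
            manifest["timing_s"]["simulate"] = round(time.perf_counter() - t0, 2)
        if sim is None:
            raise ValueError("stages after 'simulate' need the simulate stage "
                             "in this pipeline (file-based resume not enabled)")

        if "covariates" in config.stages:
            t0 = time.perf_counter()
            design = sim.fgc.design
            zpath = os.path.join(config.outdir, "zconsts.json")
            with open(zpath, "w") as fh:
                json.dump({k: list(v) for k, v in design.zconsts.items()}, fh)
            manifest["files"]["zconsts.json"] = {"path": zpath, "rows": len(design.zconsts)}
            save_df("design.csv", pd.DataFrame(design.X, columns=design.columns)
                    .assign(log_fgc=design.y, female_id=design.female_labels[design.fid]))
            manifest["timing_s"]["covariates"] = round(time.perf_counter() - t0, 2)

        if "dsi" in config.stages:
            t0 = time.perf_counter()
            rosters = pd.read_csv(os.path.join(config.outdir, "rosters.csv"))
            dsi = sociality.dsi_from_tables(sim.grooming, sim.effort, rosters,
                                            sim.cohort.females)
            dsi = sociality.impute_missing_dsi(dsi)
            save_df("dsi.csv", dsi)
            manifest["timing_s"]["dsi"] = round(time.perf_counter() - t0, 2)

        lmm = None
        if "fit_longitudinal" in config.stages:
            t0 = time.perf_counter()
            lmm = fit_lmm(sim.fgc.design)
            marg, cond = r2_nakagawa(lmm, sim.fgc.design)
            summary = lmm.summary().assign(parameter=lambda d: d.index)
            save_df("lmm_summary.csv", summary.reset_index(drop=True))
            save_df("lmm_random_effects.csv",
                    pd.DataFrame(lmm.b, columns=["b0", "b1"])
                    .assign(female_id=lmm.female_labels))
            jpath = os.path.join(config.outdir, "lmm_fit.json")
            with open(jpath, "w") as fh:
                json.dump({"marginal_r2": marg, "conditional_r2": cond,
                           "sigma2": lmm.sigma2,
                           "Sigma_b": lmm.Sigma_b.tolist(),
                           "loglik": lmm.loglik}, fh, indent=1)
            manifest["files"]["lmm_fit.json"] = {"path": jpath, "rows": 1}
            manifest["timing_s"]["fit_longitudinal"] = round(time.perf_counter() - t0, 2)

        jfit = None
        if "fit_joint" in config.stages:
            t0 = time.perf_counter()
            data = build_joint_data(sim.fgc.design, sim.fgc.year_table,
                                    sim.records, assoc_mode=config.assoc_mode)
            mcmc = MCMCConfig(seed=config.seed, **config.mcmc)
            jfit = fit_joint(data, mcmc_config=mcmc, init=lmm)
            save_df(f"joint_draws_{config.assoc_mode}.csv", jfit.draws)
            save_df(f"joint_summary_{config.assoc_mode}.csv",
                    jfit.summary().reset_index())
            manifest["timing_s"]["fit_joint"] = round(time.perf_counter() - t0, 2)

        if "predict" in config.stages:
            if jfit is None:
                raise ValueError("predict requires the fit_joint stage")
            t0 = time.perf_counter()
            pr = config.predict
            grid = np.arange(pr["t0"], pr["grid_max"] + 1e-9, pr["grid_step"])
            med = {}
            for pct in pr["percentiles"]:
                spec = percentile_trajectory(sim.fgc.samples, pct, pr["t0"],
                                             sim.fgc.design)
                curve = conditional_survival(
                    jfit, spec, grid,
                    rng=np.random.default_rng(config.seed + 1000 + int(pct)))
                save_df(f"survival_curve_p{int(pct)}.csv", curve.as_frame())
                med[int(pct)] = median_survival_age(curve)
            jpath = os.path.join(config.outdir, "median_survival_ages.json")
            with open(jpath, "w") as fh:
                json.dump(med, fh, indent=1)
            manifest["files"]["median_survival_ages.json"] = {"path": jpath,
                                                              "rows": len(med)}
            manifest["timing_s"]["predict"] = round(time.perf_counter() - t0, 2)

        if "report" in config.stages and jfit is not None:
            save_df("report.csv", jfit.summary().reset_index())
            save_df("diagnostics.csv", diagnostics(jfit).reset_index())

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        _write_manifest(config, manifest)
        root.removeHandler(handler)
        raise
    _write_manifest(config, manifest)
    root.removeHandler(handler)
    return manifest


def _write_manifest(config: PipelineConfig, manifest: dict):
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
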