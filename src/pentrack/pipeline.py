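"""End-to-end pipeline runner: raw positional streams -> behaviour table ->
repeatability, predictability (CVp) and syndrome correlations, with a
machine-readable run manifest.

Each stage persists its artifact as soon as it completes, so a failure
leaves the earlier outputs on disk; the raised :class:`StageError` names
the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dhglm import (DHGLMSpec, MCMCSettings, compute_cvp,
                    convergence_diagnostics, extract_correlations, fit_dhglm,
                    fit_mv_dhglm)
from .geometry import PenGeometry
from .io import (load_config, read_exclusion_windows, read_table,
                 read_trajectories, write_table)
from .metrics import BEHAVIOURS, MetricsConfig, build_behaviour_table
from .preprocess import (apply_exclusion_windows, moving_average_smooth,
                         remove_out_of_pen)
from .repeatability import (LMMSpec, adjusted_repeatability,
                            bootstrap_repeatability_ci, fit_lmm_reml)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "preprocess_all"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    trajectories: str
    covariates: str
    outdir: str
    temperature: str | None = None
    exclusion_windows: str | None = None
    pen: PenGeometry = field(default_factory=PenGeometry.default)
    smoothing_window_s: float = 10.0
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    behaviours: tuple[str, ...] = BEHAVIOURS
    lmm_fixed_effects: tuple[str, ...] = ()
    lmm_interaction: bool = False
    n_boot: int = 1000
    dhglm_fixed_effects: tuple[str, ...] = ()
    re_structure: str = "correlated"
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    mv_mcmc: MCMCSettings = field(default_factory=MCMCSettings.multivariate)
    run_dhglm: bool = True
    run_multivariate: bool = True
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = load_config(path)
        raw.update(overrides)
        if "pen" in raw and isinstance(raw["pen"], dict):
            raw["pen"] = PenGeometry.from_dict(raw["pen"])
        if "metrics" in raw and isinstance(raw["metrics"], dict):
            raw["metrics"] = MetricsConfig(**raw["metrics"])
        for key in ("mcmc", "mv_mcmc"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = MCMCSettings(**raw[key])
        for key in ("behaviours", "lmm_fixed_effects", "dhglm_fixed_effects"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def canonical(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, PenGeometry):
                d[k] = v.to_dict()
            elif hasattr(v, "__dict__"):
                d[k] = {kk: vv for kk, vv in v.__dict__.items()}
            else:
                d[k] = list(v) if isinstance(v, tuple) else v
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def preprocess_all(trajectories, pen, windows, smoothing_window_s):
    """Exclusion windows -> out-of-pen filter -> moving-average smoothing,
    the canonical processing order."""
    out = []
    for tr in trajectories:
        tr = apply_exclusion_windows(tr, windows)
        tr = remove_out_of_pen(tr, pen)
        if len(tr) == 0:
            logger.warning("no samples left for %s after filtering",
                           tr.individual_id)
            continue
        out.append(moving_average_smooth(tr, smoothing_window_s))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output bundle (also written under
    ``config.outdir``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise StageError(name, exc) from exc
        return _Ctx()

    with stage("load"):
        trajs = read_trajectories(config.trajectories)
        covariates = read_table(config.covariates)
        temperature = (read_table(config.temperature)
                       if config.temperature else None)
        windows = (read_exclusion_windows(config.exclusion_windows)
                   if config.exclusion_windows else [])
        if not trajs:
            raise ValueError(f"no trajectories in {config.trajectories}")

    with stage("preprocess"):
        trajs = preprocess_all(trajs, config.pen, windows,
                               config.smoothing_window_s)

    with stage("metrics"):
        table = build_behaviour_table(trajs, covariates, config.pen,
                                      temperature, config.metrics)
        if table.empty:
            raise ValueError("behaviour table is empty")
        write_table(table, outdir / "behaviour_table.csv")
        bundle["behaviour_table"] = table

    with stage("repeatability"):
        rows = []
        for beh in config.behaviours:
            spec = LMMSpec(response=beh,
                           fixed_effects=config.lmm_fixed_effects,
                           cohort_unit_interaction=config.lmm_interaction)
            fit = fit_lmm_reml(table, spec)
            if config.n_boot > 0:
                est = bootstrap_repeatability_ci(
                    table, spec, n_boot=config.n_boot, seed=config.seed)
            else:
                est = adjusted_repeatability(fit)
            rows.append(dict(behaviour=beh, r=est.r, ci_low=est.ci_low,
                             ci_high=est.ci_high, v_ind=fit.v_ind,
                             v_res=fit.v_res, n=fit.n_individuals,
                             converged=fit.converged, singular=fit.singular))
        rep = pd.DataFrame(rows)
        write_table(rep, outdir / "repeatability.csv")
        bundle["repeatability"] = rep

    diag_frames = []
    if config.run_dhglm:
        with stage("dhglm"):
            rows = []
            for i, beh in enumerate(config.behaviours):
                spec = DHGLMSpec(responses=(beh,),
                                 fixed_effects=config.dhglm_fixed_effects,
                                 re_structure=config.re_structure)
                settings = MCMCSettings(
                    n_chains=config.mcmc.n_chains, n_iter=config.mcmc.n_iter,
                    burn_in=config.mcmc.burn_in, thin=config.mcmc.thin,
                    seed=config.seed + 1000 + i)
                fit = fit_dhglm(table, spec, settings)
                cvp = compute_cvp(fit, beh)
                rows.append(dict(behaviour=beh, cvp=cvp.cvp,
                                 cri_low=cvp.cri_low, cri_high=cvp.cri_high))
                d = convergence_diagnostics(fit)
                d.insert(0, "model", f"dhglm:{beh}")
                diag_frames.append(d)
                write_table(fit.draws_frame(),
                            outdir / f"posterior_draws_{beh}.csv")
            cvp_table = pd.DataFrame(rows)
            write_table(cvp_table, outdir / "cvp.csv")
            bundle["cvp"] = cvp_table

    if config.run_multivariate and len(config.behaviours) >= 2:
        with stage("multivariate"):
            mv_settings = MCMCSettings(
                n_chains=config.mv_mcmc.n_chains,
                n_iter=config.mv_mcmc.n_iter,
                burn_in=config.mv_mcmc.burn_in, thin=config.mv_mcmc.thin,
                seed=config.seed + 2000)
            mv = fit_mv_dhglm(table, config.behaviours, mv_settings,
                              fixed_effects=config.dhglm_fixed_effects)
            report = extract_correlations(mv, "all")
            write_table(report.rows, outdir / "correlations.csv")
            bundle["correlations"] = report.rows
            d = convergence_diagnostics(mv)
            d.insert(0, "model", "multivariate")
            diag_frames.append(d)
            write_table(mv.draws_frame(),
                        outdir / "posterior_draws_multivariate.csv")

    if diag_frames:
        diagnostics = pd.concat(diag_frames, ignore_index=True)
        write_table(diagnostics, outdir / "diagnostics.csv")
        bundle["diagnostics"] = diagnostics

    manifest = dict(
        package_version=__version__,
        numpy_version=np.__version__,
        pandas_version=pd.__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        config=config.canonical(),
        timings_s=timings,
    )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    bundle["manifest"] = manifest
    return bundle
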