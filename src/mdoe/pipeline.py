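"""Pipeline orchestration: calibrate → plan → simulate → evaluate → recommend.

A :class:`StudyConfig` (usually loaded from YAML) resolves the study kind
(``S1``, ``S2`` or ``toy``), the dataset (a CSV or a synthetic study), and
the per-stage settings.  :func:`run_pipeline` executes the stages in order,
writes every artifact as CSV plus a machine-readable run log, and is a pure
function of (config, master seed): two runs with identical inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from mdoe import io
from mdoe.calibration import (
    CalibrationConfig,
    MeasurementDataset,
    NoiseSpec,
    ParameterEnsemble,
    build_ensemble,
)
from mdoe.design import Design, DesignSpace, plan_design
from mdoe.desirability import (
    DesirabilityConfig,
    DesirabilityRanking,
    fit_response_surface,
    rank_and_select,
    response_surface_grid,
)
from mdoe.errors import ConfigurationError, MdoeError
from mdoe.mc import ResponseSpec, evaluate_design
from mdoe.scenario import Scenario
from mdoe.synthetic import (
    generate_synthetic_study,
    s1_scenario,
    s2_scenario,
    study_design_space,
    study_response,
)
from mdoe.toy import generate_toy_dataset, toy_design_space, toy_response, toy_scenario

#: Default free-parameter subsets per study kind: the rate/yield parameters
#: the corresponding observables actually identify.
DEFAULT_FREE_PARAMS = {
    "S1": ("qGlc_ox_max", "qGlc_ferm_max", "qEtOH_max", "Y_XS_ox", "Glc_crab"),
    "S2": ("qEAA_max", "EAA_inhib_50", "qGlc_ox_max", "Y_XS_ox"),
    "toy": ("q_max", "Y_XS"),
}


@dataclass
class StudyConfig:
    """Resolved configuration of one mDoE study."""

    kind: str
    scenario: Scenario
    dataset: MeasurementDataset
    space: DesignSpace
    factor_paths: list[str]
    response: ResponseSpec
    calibration: CalibrationConfig
    noise: NoiseSpec
    design_k: int = 29
    design_n_random: int = 100_000
    design_seed: int | None = None  # None: spawned from the master seed
    mc_n_sims: int = 30
    mc_seed: int | None = None
    desirability: DesirabilityConfig = field(default_factory=DesirabilityConfig)
    master_seed: int = 0
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "StudyConfig":
        """Build a study from a nested config mapping (YAML layout).

        Sections: ``study`` (kind, master_seed), ``dataset`` (path or
        synthetic seed), ``calibration``, ``design``, ``mc``, ``response``,
        ``desirability``, ``noise``.  Every omitted setting falls back to
        the study-kind default.
        """
        study = cfg.get("study", {})
        kind = study.get("kind", "S1")
        if kind not in ("S1", "S2", "toy"):
            raise ConfigurationError(f"unknown study kind {kind!r}")
        master_seed = int(study.get("master_seed", 0))

        if kind == "toy":
            scenario = toy_scenario()
            space, paths = toy_design_space()
            response = toy_response()
        else:
            scenario = s1_scenario() if kind == "S1" else s2_scenario()
            space, paths = study_design_space(kind)
            response = study_response(kind)

        noise_cfg = cfg.get("noise", {})
        noise = NoiseSpec(
            measurement_rel=noise_cfg.get("measurement_rel"),
            initial_rel=noise_cfg.get("initial_rel", 0.05),
            compartment_rel=noise_cfg.get("compartment_rel", 0.10),
            setpoint_rel=noise_cfg.get("setpoint_rel", 0.05),
        )

        ds_cfg = cfg.get("dataset", {})
        if "path" in ds_cfg:
            path = Path(ds_cfg["path"])
            if not path.exists():
                raise ConfigurationError(f"dataset path {path} does not exist")
            initial = {k: (float(v), float("nan")) for k, v in scenario.initial.items() if v > 0}
            dataset = io.read_dataset(path, initial=initial)
        elif kind == "toy":
            dataset = generate_toy_dataset(seed=int(ds_cfg.get("seed", master_seed)))
        else:
            dataset = generate_synthetic_study(
                kind=kind, noise=noise, seed=int(ds_cfg.get("seed", master_seed))
            ).dataset

        cal_cfg = cfg.get("calibration", {})
        calibration = CalibrationConfig(
            free_params=tuple(cal_cfg.get("free_params", DEFAULT_FREE_PARAMS[kind])),
            n_fits=int(cal_cfg.get("n_fits", 116 if kind != "toy" else 8)),
            n_starts=int(cal_cfg.get("n_starts", 3)),
            maxiter=int(cal_cfg.get("maxiter", 200)),
            seed=int(cal_cfg.get("seed", master_seed)),
        )

        r_cfg = cfg.get("response")
        if r_cfg:
            response = ResponseSpec(
                observable=r_cfg["observable"],
                reduction=r_cfg.get("reduction", "value_at_time"),
                at_time=r_cfg.get("at_time", 48.0),
            )

        des_cfg = cfg.get("desirability", {})
        desirability = DesirabilityConfig(
            w1=float(des_cfg.get("w1", 0.8)),
            w2=float(des_cfg.get("w2", 0.2)),
            n_select=int(des_cfg.get("n_select", 4)),
        )

        d_cfg = cfg.get("design", {})
        m_cfg = cfg.get("mc", {})
        return cls(
            kind=kind,
            scenario=scenario,
            dataset=dataset,
            space=space,
            factor_paths=list(paths),
            response=response,
            calibration=calibration,
            noise=noise,
            design_k=int(d_cfg.get("k", 29)),
            design_n_random=int(d_cfg.get("n_random", 100_000)),
            design_seed=None if "seed" not in d_cfg else int(d_cfg["seed"]),
            mc_n_sims=int(m_cfg.get("n_sims", 30)),
            mc_seed=None if "seed" not in m_cfg else int(m_cfg["seed"]),
            desirability=desirability,
            master_seed=master_seed,
            raw=dict(cfg),
        )


@dataclass
class PipelineResult:
    ensemble: ParameterEnsemble
    design: Design
    summaries: pd.DataFrame
    ranking: DesirabilityRanking
    rs_r2: float | None
    log: dict[str, Any]


def run_pipeline(
    cfg: StudyConfig, outdir: str | Path | None = None, seed: int | None = None
) -> PipelineResult:
    """Run calibrate → plan → simulate → evaluate → recommend.

    ``seed`` overrides the config's master seed; one seed sequence spawns
    independent per-stage substreams.  Artifacts written to ``outdir``:
    ``ensemble.csv``, ``ensemble_summary.csv``, ``design.csv``,
    ``responses.csv``, ``ranking.csv``, ``rs_grid_<x>_<y>.csv`` and
    ``run_log.json``.  Any stage failure aborts with the stage name; the
    artifacts of completed stages remain on disk.
    """
    master = cfg.master_seed if seed is None else int(seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(master).spawn(4)]
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: dict[str, Any] = {"master_seed": master, "kind": cfg.kind, "stages": {}}

    def _stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **counts}

        return done

    try:
        done = _stage("calibrate")
        cal = CalibrationConfig(
            free_params=cfg.calibration.free_params,
            n_fits=cfg.calibration.n_fits,
            n_starts=cfg.calibration.n_starts,
            maxiter=cfg.calibration.maxiter,
            seed=stage_seeds[0],
        )
        ensemble = build_ensemble(cfg.scenario, cfg.dataset, cfg.noise, cal)
        done(n_fits=int(len(ensemble.members)))
        if out is not None:
            io.write_ensemble(ensemble, out / "ensemble.csv", out / "ensemble_summary.csv")
    except MdoeError as exc:
        raise MdoeError(f"stage 'calibrate' failed: {exc}") from exc

    try:
        done = _stage("plan")
        design = plan_design(
            cfg.space,
            k=cfg.design_k,
            n_random=cfg.design_n_random,
            seed=stage_seeds[1] if cfg.design_seed is None else cfg.design_seed,
        )
        done(k=design.k, n_random=cfg.design_n_random)
        if out is not None:
            io.write_design(design, out / "design.csv")
    except MdoeError as exc:
        raise MdoeError(f"stage 'plan' failed: {exc}") from exc

    try:
        done = _stage("simulate_design")
        # simulate around the ensemble median so non-free parameters stay nominal
        base = cfg.scenario.params.replace(**ensemble.median_values())
        scenario = Scenario(
            cfg.scenario.model,
            base,
            cfg.scenario.initial,
            cfg.scenario.feeds,
            cfg.scenario.env,
            cfg.scenario.t_grid,
        )
        summaries = evaluate_design(
            design,
            cfg.factor_paths,
            ensemble,
            scenario,
            cfg.response,
            n_sims=cfg.mc_n_sims,
            seed=stage_seeds[2] if cfg.mc_seed is None else cfg.mc_seed,
        )
        done(n_sims=cfg.mc_n_sims, n_fail=int(summaries["n_fail"].sum()))
        if out is not None:
            summaries.to_csv(out / "responses.csv", index=False)
    except MdoeError as exc:
        raise MdoeError(f"stage 'simulate_design' failed: {exc}") from exc

    try:
        done = _stage("recommend")
        ranking = rank_and_select(summaries, cfg.desirability)
        rs_r2 = None
        n_terms = 1 + 2 * len(cfg.space.factors) + len(cfg.space.factors) * (len(cfg.space.factors) - 1) // 2
        if design.k >= n_terms:
            rs = fit_response_surface(design, ranking.table["D"].to_numpy())
            rs_r2 = rs.r2
            if out is not None and len(cfg.space.factors) >= 2:
                best = ranking.best
                fixed = {n: float(best[n]) for n in cfg.space.names}
                names = cfg.space.names
                for i in range(len(names)):
                    for j in range(i + 1, len(names)):
                        grid = response_surface_grid(rs, design, names[i], names[j], fixed)
                        grid.to_csv(out / f"rs_grid_{names[i]}_{names[j]}.csv", index=False)
        done(n_select=cfg.desirability.n_select, rs_r2=rs_r2)
        if out is not None:
            ranking.table.to_csv(out / "ranking.csv", index=False)
    except MdoeError as exc:
        raise MdoeError(f"stage 'recommend' failed: {exc}") from exc

    log["counts"] = {
        "n_fits": int(len(ensemble.members)),
        "k": design.k,
        "n_sims": cfg.mc_n_sims,
        "n_fail": int(summaries["n_fail"].sum()),
    }
    if out is not None:
        io.write_run_log(log, out / "run_log.json")
    return PipelineResult(
        ensemble=ensemble,
        design=design,
        summaries=summaries,
        ranking=ranking,
        rs_r2=rs_r2,
        log=log,
    )
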