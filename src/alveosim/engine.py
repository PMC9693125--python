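"""Simulation engine: multi-rate schedule, recording, sweeps.

The base schedule follows the reference timing: a 1 s diffusion step,
biological behaviours every 10 diffusion steps, standalone tissue operations
every 10 s and a time-series record every hour.  Long experiments (hundreds
of simulated days) run in *coarse* mode: biological evaluations every hour
(all hazards are per-hour rates converted with p = 1 - exp(-rate dt), so the
statistics are step-size invariant) with diffusion sub-stepped at the
largest stable dt between evaluations.

Behaviour categories execute in a fixed order each biological step —
secretion, bystander, damaged maturation, phagocytosis, migration,
proliferation, differentiation, apoptosis — with agent-level draw order
randomised where sequential conflicts exist.  Dead cells are removed at the
end of their category; daughters act from the next evaluation.  A run is a
pure function of (config, plan, seed): identical inputs give bit-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration
from .agents import (
    BystanderParams,
    ClearanceParams,
    RateTable,
    EpithelialHood,
    apoptose,
    differentiate,
    enforce_min_separation,
    mature_damaged,
    migrate_informed,
    migrate_random,
    phagocytose,
    proliferate,
    secrete,
    update_bystander,
)
from .geometry import GeometryConfig, build_duct
from .irradiation import IrradiationPlan, LQParams, apply_irradiation, calibrate_lq
from .population import DEFAULT_INITIAL_COUNTS, Population, seed_cells
from .substances import FieldSet, SUBSTANCE_NAMES
from .tissue_ops import (
    InfluxSpec,
    count_surviving_alveoli,
    fibroblast_influx,
    il13_source,
    monocyte_influx,
)

__all__ = ["SimulationConfig", "Simulation", "RunResult", "run", "sweep", "write_outputs"]

CATEGORIES = (
    "secretion",
    "bystander",
    "maturation",
    "phagocytosis",
    "migration",
    "proliferation",
    "differentiation",
    "apoptosis",
)


@dataclass
class SimulationConfig:
    seed: int = 0
    duration_days: float = 30.0
    # base-mode schedule (seconds)
    dt_diffusion_s: float = 1.0
    behavior_period: int = 10
    ops_period_s: float = 10.0
    record_period_s: float = 3600.0
    # coarse mode
    coarse: bool = True
    dt_bio_h: float = 1.0
    record_every_h: float = 24.0
    diffusion_substep_s: float = 400.0
    # early stop for long post-irradiation runs: the duct state is frozen
    # w.r.t. alveolus survival once the injury has resolved (see docs)
    early_stop: bool = False
    early_stop_min_days: float = 500.0
    early_stop_quiet_days: float = 100.0
    # field initialisation
    burnin_hours: float = 400.0
    calibration_rounds: int = 2
    # components
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    initial_counts: dict = field(default_factory=lambda: dict(DEFAULT_INITIAL_COUNTS))
    rates: RateTable = field(default_factory=calibration.default_rate_table)
    bystander: BystanderParams = field(default_factory=BystanderParams)
    clearance: ClearanceParams = field(default_factory=ClearanceParams)
    influx: InfluxSpec = field(default_factory=calibration.default_influx_spec)
    lq: LQParams = field(default_factory=calibrate_lq)

    def __post_init__(self):
        if self.coarse and self.dt_bio_h > 1.0:
            raise ValueError("coarse biological step must not exceed 1 h")
        for period in (self.behavior_period * self.dt_diffusion_s, self.ops_period_s,
                       self.record_period_s):
            ratio = period / self.dt_diffusion_s
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError("schedule periods must be integer multiples of dt_diffusion")


@dataclass
class RunResult:
    timeseries: pd.DataFrame
    population: Population
    damage_report: object | None
    config: SimulationConfig
    plan: IrradiationPlan | None
    baseline_ecm: float

    @property
    def surviving_alveoli(self) -> int:
        return count_surviving_alveoli(self.population)


class Simulation:
    """One seeded realisation of the duct."""

    def __init__(self, config: SimulationConfig, plan: IrradiationPlan | None = None,
                 step_listener=None):
        self.config = config
        self.plan = plan
        self.rng = np.random.default_rng(config.seed)
        self.duct = build_duct(config.geometry)
        self.pop = seed_cells(
            self.duct,
            config.initial_counts,
            self.rng,
            phagocytic_fraction=config.clearance.phagocytic_fraction,
            phagocytic_index=config.clearance.phagocytic_index,
        )
        self.fields = FieldSet(calibration.default_substance_specs(), config.geometry)
        if config.burnin_hours > 0:
            calibration.equilibrate_fields(
                self.fields, self.pop, config.rates, config.influx, hours=config.burnin_hours
            )
        if config.calibration_rounds > 0:
            calibration.calibrate_field_response(
                self.fields, self.pop, config.rates, config.influx,
                rounds=config.calibration_rounds,
            )
        enforce_min_separation(self.pop, self.rng)
        self.t_h = 0.0
        self.delivered = False
        self.damage_report = None
        self.baseline_ecm = self.fields.mean_concentration("ECM")
        self.records: list = []
        self.n_behavior_evals = 0
        self.step_listener = step_listener
        self._record()

    # -- recording ------------------------------------------------------
    def _record(self) -> None:
        row = {"t_hours": self.t_h}
        for name, c in self.pop.counts().items():
            row[f"n_{name}"] = c
        for name in SUBSTANCE_NAMES:
            row[f"conc_{name}"] = self.fields.mean_concentration(name)
        row["n_surviving_alveoli"] = count_surviving_alveoli(self.pop)
        self.records.append(row)

    def timeseries(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.records)

    # -- one biological evaluation --------------------------------------
    def step_bio(self, dt_h: float) -> None:
        cfg = self.config
        pop, fields, rng = self.pop, self.fields, self.rng
        self.n_behavior_evals += 1
        notify = self.step_listener or (lambda category, sim: None)

        secrete(pop, fields, cfg.rates, dt_h)
        notify("secretion", self)
        update_bystander(pop, cfg.bystander, rng, dt_h)
        notify("bystander", self)
        mature_damaged(pop, dt_h)
        notify("maturation", self)
        eaten = phagocytose(pop, cfg.clearance, rng)
        pop.remove(eaten)
        notify("phagocytosis", self)
        migrate_random(pop, cfg.rates, rng, dt_h)
        # one snapshot of the epithelial sheet per step: informed migration
        # senses it simultaneously, and the density-feedback categories reuse
        # it (this-step daughters act next step)
        hood = EpithelialHood(pop)
        migrate_informed(pop, cfg.rates, dt_h, hood=hood)
        enforce_min_separation(pop, rng, passes=1)
        notify("migration", self)
        proliferate(pop, fields, cfg.rates, rng, dt_h, hood=hood)
        notify("proliferation", self)
        differentiate(pop, fields, cfg.rates, rng, dt_h)
        notify("differentiation", self)
        doomed = apoptose(pop, cfg.rates, rng, dt_h, hood=hood)
        pop.remove(doomed)
        notify("apoptosis", self)

    def step_ops(self, dt_h: float) -> None:
        cfg = self.config
        il13_source(self.fields, self.duct, cfg.influx, dt_h)
        fibroblast_influx(self.pop, cfg.influx, self.rng, dt_h)
        monocyte_influx(
            self.pop, self.fields, cfg.influx, self.rng, dt_h,
            phagocytic_fraction=cfg.clearance.phagocytic_fraction,
            phagocytic_index=cfg.clearance.phagocytic_index,
        )

    def _maybe_deliver(self) -> None:
        if self.plan is None or self.plan.dose_gy == 0.0:
            return
        if self.t_h + 1e-9 >= self.plan.time_of_delivery_h and not self.delivered:
            self.damage_report = apply_irradiation(
                self.pop, self.plan, self.config.lq, self.rng, self.config.bystander
            )
            self.delivered = True

    # -- drivers ---------------------------------------------------------
    def run(self) -> RunResult:
        return self.run_coarse() if self.config.coarse else self.run_base()

    def run_base(self) -> RunResult:
        """Reference schedule: 1 s diffusion, 10 s biology/ops, hourly records."""
        cfg = self.config
        dt = cfg.dt_diffusion_s
        n_steps = int(round(cfg.duration_days * 86400.0 / dt))
        bio_every = cfg.behavior_period
        ops_every = int(round(cfg.ops_period_s / dt))
        rec_every = int(round(cfg.record_period_s / dt))
        self._maybe_deliver()
        for k in range(1, n_steps + 1):
            self.fields.step_diffusion(dt)
            if k % bio_every == 0:
                self.step_bio(bio_every * dt / 3600.0)
            if k % ops_every == 0:
                self.step_ops(ops_every * dt / 3600.0)
            self.t_h = k * dt / 3600.0
            self._maybe_deliver()
            if k % rec_every == 0:
                self._record()
        return self._result()

    def run_coarse(self) -> RunResult:
        cfg = self.config
        dt_h = cfg.dt_bio_h
        n_steps = int(round(cfg.duration_days * 24.0 / dt_h))
        rec_every = max(1, int(round(cfg.record_every_h / dt_h)))
        quiet_h = 0.0
        self._maybe_deliver()
        for k in range(1, n_steps + 1):
            self.fields.advance(dt_h * 3600.0, max_substep=cfg.diffusion_substep_s)
            self.step_bio(dt_h)
            self.step_ops(dt_h)
            self.t_h = k * dt_h
            self._maybe_deliver()
            if k % rec_every == 0:
                self._record()
            if cfg.early_stop and self.delivered:
                c = self.pop.counts()
                if c["AEC2_damaged"] + c["AEC2_senescent"] == 0:
                    quiet_h += dt_h
                else:
                    quiet_h = 0.0
                if (
                    self.t_h >= cfg.early_stop_min_days * 24.0
                    and quiet_h >= cfg.early_stop_quiet_days * 24.0
                ):
                    if k % rec_every != 0:
                        self._record()
                    break
        return self._result()

    def _result(self) -> RunResult:
        return RunResult(
            timeseries=self.timeseries(),
            population=self.pop,
            damage_report=self.damage_report,
            config=self.config,
            plan=self.plan,
            baseline_ecm=self.baseline_ecm,
        )


def run(config: SimulationConfig, plan: IrradiationPlan | None = None) -> RunResult:
    return Simulation(config, plan).run()


def derive_seed(base_seed: int, dose_index: int, replicate: int) -> int:
    """Deterministic per-run seed, kept below 2**31."""
    ss = np.random.SeedSequence([base_seed, dose_index, replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def sweep(
    doses,
    replicates: int,
    config: SimulationConfig,
    *,
    senescent_fraction: float = 1.0,
    early_timepoint_days: float = 90.0,
) -> pd.DataFrame:
    """Independent seeded runs per (dose, replicate); one summary row each.

    Columns: dose_gy, replicate, seed, surviving_alveoli, survival_fraction,
    delta_ecm_early (at ``early_timepoint_days``), delta_ecm_late (final
    record) — all in g/cm^3 against the run's own pre-irradiation baseline.
    """
    from dataclasses import replace

    doses = list(doses)
    if not doses:
        raise ValueError("need at least one dose")
    rows = []
    for di, dose in enumerate(doses):
        for rep in range(replicates):
            seed = derive_seed(config.seed, di, rep)
            cfg = replace(config, seed=seed)
            plan = IrradiationPlan(dose_gy=float(dose), senescent_fraction=senescent_fraction)
            res = Simulation(cfg, plan).run()
            ts = res.timeseries
            i_early = (ts["t_hours"] - early_timepoint_days * 24.0).abs().idxmin()
            rows.append(
                {
                    "dose_gy": float(dose),
                    "replicate": rep,
                    "seed": seed,
                    "surviving_alveoli": res.surviving_alveoli,
                    "survival_fraction": res.surviving_alveoli / res.population.duct.n_alveoli,
                    "delta_ecm_early": float(ts["conc_ECM"].iloc[i_early] - res.baseline_ecm),
                    "delta_ecm_late": float(ts["conc_ECM"].iloc[-1] - res.baseline_ecm),
                }
            )
    return pd.DataFrame(rows)


def write_outputs(result: RunResult, outdir) -> None:
    """timeseries.csv, alveoli.csv, damage_report.csv and run_meta.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.timeseries.to_csv(out / "timeseries.csv", index=False)
    per_alv = result.population.healthy_aec2_per_alveolus()
    pd.DataFrame(
        {
            "alveolus_id": np.arange(per_alv.size),
            "n_healthy_aec2": per_alv,
            "survived": (per_alv > 0).astype(int),
        }
    ).to_csv(out / "alveoli.csv", index=False)
    if result.damage_report is not None:
        pd.DataFrame(result.damage_report.as_dict()).to_csv(
            out / "damage_report.csv", index=False
        )
    meta = {
        "seed": result.config.seed,
        "duration_days": result.config.duration_days,
        "coarse": result.config.coarse,
        "dose_gy": result.plan.dose_gy if result.plan else 0.0,
        "senescent_fraction": result.plan.senescent_fraction if result.plan else None,
        "lq": {"alpha": result.config.lq.alpha, "beta": result.config.lq.beta},
        "baseline_ecm": result.baseline_ecm,
        "surviving_alveoli": int(result.surviving_alveoli),
    }
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
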