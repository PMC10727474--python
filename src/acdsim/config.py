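"""Run configuration: YAML loading, validation and defaults.

Every open parameter of the simulator and the interface model is a config
key with a documented default; an empty file yields the default run.
Unknown keys and out-of-range values are rejected with errors naming the
offending key, and the fully-resolved configuration is echoed into the run
metadata so every default actually used is machine-visible.
"""

from __future__ import annotations

import pathlib
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import interface
from .diffusion import DiffusionModel, FactorId, KernelParams
from .dynamics import StepConfig
from .experiments import CentreFill, GeometryConfig, Scenario
from .fitness import FitnessParams, check_fitness_orderings

__all__ = ["RunConfig", "load_config", "save_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DynamicsSection(_Section):
    p_death: float = Field(0.05, ge=0.0, le=1.0)
    immune_alpha: float = Field(0.1, ge=0.0, le=1.0)
    mutation_rate: float = Field(1e-5, ge=0.0, le=1.0)


class DiffusionSection(_Section):
    base_radius: dict[str, float] = {"gf1": 2.0, "gf2": 4.0, "gf3": 6.0, "lactate": 3.0}
    mass: dict[str, float] = {"gf1": 1.0, "gf2": 1.0, "gf3": 1.0, "lactate": 3.0}
    model_scale: dict[str, float] = {"a": 1.0, "b": 0.5, "c": 2.0}
    flat: bool = False

    @model_validator(mode="after")
    def _check(self) -> "DiffusionSection":
        for key, d, expected in (
            ("base_radius", self.base_radius, {"gf1", "gf2", "gf3", "lactate"}),
            ("mass", self.mass, {"gf1", "gf2", "gf3", "lactate"}),
            ("model_scale", self.model_scale, {"a", "b", "c"}),
        ):
            if set(d) != expected:
                raise ValueError(f"{key} must have keys {sorted(expected)}, got {sorted(d)}")
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"{key}.{k} must be positive, got {v}")
        return self


class FitnessSection(_Section):
    w_base: float = Field(1.0, gt=0.0)
    benefit_slope: tuple[float, float, float] = (1.0, 1.0, 1.0)
    production_cost: tuple[float, float, float] = (0.3, 0.3, 0.3)
    lactate_production_cost: float = Field(0.05, ge=0.0)
    lactate_damage: float = Field(0.3, ge=0.0)
    mutation_penalty: float = Field(0.05, ge=0.0)
    floor: float = Field(1e-9, ge=0.0)


class ScenarioSection(_Section):
    centre_fill: Literal["NORMAL_CONTROL", "HT_WARBURG", "HT_NO_WARBURG"] = "HT_NO_WARBURG"
    drug_on: bool = False
    model: Literal["A", "B", "C"] = "A"
    n_steps: int = Field(10_000, ge=1)
    n_replicates: int = Field(500, ge=1)


class GeometrySection(_Section):
    height: int = Field(100, ge=1)
    width: int = Field(100, ge=1)
    ring_h: int = Field(22, ge=1)
    ring_w: int = Field(22, ge=1)
    hole_h: int = Field(7, ge=1)
    hole_w: int = Field(12, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "GeometrySection":
        if self.ring_h > self.height or self.ring_w > self.width:
            raise ValueError("ring_h/ring_w: cancer ring does not fit in the field")
        if self.hole_h > self.ring_h or self.hole_w > self.ring_w:
            raise ValueError("hole_h/hole_w: implant hole larger than the cancer ring")
        return self


class InterfaceSection(_Section):
    family: Literal["LINEAR", "LOGISTIC", "CONVEX", "CONCAVE"] = "LOGISTIC"
    k1: float = Field(5.0, gt=0.0)
    A: float = Field(1.0, gt=0.0)
    B: float = 0.0
    power: float = Field(2.0, gt=0.0)
    t_max: float = Field(5.0, gt=0.0)
    r: float = Field(0.5, gt=0.0, lt=1.0)
    g_min: float = Field(0.05, gt=0.0)
    g_max: float = Field(5.0, gt=0.0)
    n_g: int = Field(101, ge=2)
    ratio_min: float = Field(0.01, gt=0.0, lt=1.0)
    ratio_max: float = Field(0.99, gt=0.0, lt=1.0)
    n_ratio: int = Field(99, ge=2)

    @model_validator(mode="after")
    def _check(self) -> "InterfaceSection":
        if self.g_min >= self.g_max:
            raise ValueError("g_min must be below g_max")
        if self.ratio_min >= self.ratio_max:
            raise ValueError("ratio_min must be below ratio_max")
        return self


class RunConfig(_Section):
    """The full run configuration; every field has a documented default."""

    base_seed: int = 0
    out_dir: str = "results"
    snapshot_stride: int = Field(0, ge=0)  # 0 disables snapshots
    dynamics: DynamicsSection = Field(default_factory=DynamicsSection)
    diffusion: DiffusionSection = Field(default_factory=DiffusionSection)
    fitness: FitnessSection = Field(default_factory=FitnessSection)
    scenario: ScenarioSection = Field(default_factory=ScenarioSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    interface: InterfaceSection = Field(default_factory=InterfaceSection)

    # -- builders for the runtime objects ----------------------------------

    def kernel_params(self) -> KernelParams:
        d = self.diffusion
        fmap = {"gf1": FactorId.GF1, "gf2": FactorId.GF2, "gf3": FactorId.GF3,
                "lactate": FactorId.LACTATE}
        return KernelParams(
            base_radius={fmap[k]: v for k, v in d.base_radius.items()},
            mass={fmap[k]: v for k, v in d.mass.items()},
            model_scale={DiffusionModel(k.upper()): v for k, v in d.model_scale.items()},
            flat=d.flat,
        )

    def fitness_params(self) -> FitnessParams:
        f = self.fitness
        return FitnessParams(
            w_base=f.w_base,
            benefit_slope=f.benefit_slope,
            production_cost=f.production_cost,
            lactate_production_cost=f.lactate_production_cost,
            lactate_damage=f.lactate_damage,
            mutation_penalty=f.mutation_penalty,
            floor=f.floor,
        )

    def step_config(self, self_check: bool = True) -> StepConfig:
        params = self.fitness_params()
        kp = self.kernel_params()
        if self_check:
            check_fitness_orderings(params, kp.mass)
        return StepConfig(
            p_death=self.dynamics.p_death,
            immune_alpha=self.dynamics.immune_alpha,
            mutation_rate=self.dynamics.mutation_rate,
            model=DiffusionModel(self.scenario.model),
            fitness=params,
            kernel_params=kp,
        )

    def scenario_obj(self) -> Scenario:
        s = self.scenario
        return Scenario(
            centre_fill=CentreFill(s.centre_fill),
            drug_on=s.drug_on,
            model=DiffusionModel(s.model),
            n_steps=s.n_steps,
            n_replicates=s.n_replicates,
            base_seed=self.base_seed,
        )

    def geometry_obj(self) -> GeometryConfig:
        g = self.geometry
        return GeometryConfig(
            height=g.height, width=g.width,
            ring_h=g.ring_h, ring_w=g.ring_w,
            hole_h=g.hole_h, hole_w=g.hole_w,
        )

    def fitness_function(self) -> interface.FitnessFunction:
        i = self.interface
        if i.family == "LINEAR":
            return interface.LinearF(i.A, i.B)
        if i.family == "LOGISTIC":
            return interface.LogisticF.from_steepness(i.k1)
        # `power` is the convex exponent (> 1); the concave family uses its
        # reciprocal so one config key covers both shapes.
        p = i.power if i.family == "CONVEX" else 1.0 / i.power
        if (i.family == "CONVEX") != (p > 1.0):
            raise ValueError(f"power={i.power} does not give a {i.family} shape")
        return interface.PowerF(p=p, t_max=i.t_max)

    def resolved(self) -> dict:
        """The fully-resolved configuration (defaults filled in), suitable
        for the metadata log."""
        return self.model_dump(mode="json")


def load_config(path: str | pathlib.Path | None) -> RunConfig:
    """Load a YAML config file; an empty (or absent) file gives defaults."""
    if path is None:
        return RunConfig()
    raw = pathlib.Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(data)


def save_config(cfg: RunConfig, path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(yaml.safe_dump(cfg.resolved(), sort_keys=False))
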