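"""The stochastic lattice update: death, fitness-proportional birth, mutation.

One time step executes, in order:

1. concentration fields from the current producer occupancy;
2. the fitness map of every live cell;
3. a death phase — each live cell dies with probability
   ``1 - (1 - p_death) * (1 - p_imm)`` combining baseline turnover with
   immune elimination of detectably mutated cells;
4. a birth phase — every vacancy with at least one live von Neumann
   neighbour is recolonised by a copy of a neighbour chosen with probability
   proportional to its fitness (death–birth process).  Filling is
   synchronous: all parents are drawn from the pre-fill occupancy;
5. one-way mutation of every live cell at the per-locus rate;
6. class proportions and the mean mutated-allele fraction are recorded.

Randomness comes from a single ``numpy`` generator per run; the phases
consume draws in the fixed order above, so a run is bit-reproducible from
``(initial lattice, config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genotype as gt
from .diffusion import (
    DiffusionModel,
    FactorId,
    FieldComputer,
    FieldSet,
    KernelParams,
    Kernel,
    build_kernels,
    compute_fields,
)
from .fitness import DrugPolicy, FitnessParams, NO_DRUG, _FitnessTables, fitness_map

__all__ = [
    "Lattice",
    "StepConfig",
    "StepMetrics",
    "METRIC_COLUMNS",
    "death_phase",
    "birth_phase",
    "mutation_phase",
    "compute_metrics",
    "producer_masks",
    "step",
    "run",
]

#: Column order of a time-series row / DataFrame.
METRIC_COLUMNS = [
    "step",
    "live_count",
    "normal",
    "cancer",
    "hypertumour",
    "partial_hypertumour",
    "other_mutant",
    "mutation_proportion",
]

_PROD_LOCI = {
    FactorId.GF1: "prod_gf1",
    FactorId.GF2: "prod_gf2",
    FactorId.GF3: "prod_gf3",
    FactorId.LACTATE: "prod_lactate",
}


@dataclass
class Lattice:
    """Grid of occupants: a 9-bit genotype code per site plus a live mask.

    ``geno`` values at vacant sites are stale and must be ignored.
    """

    geno: np.ndarray  # uint16, shape (height, width)
    alive: np.ndarray  # bool, same shape

    @classmethod
    def full(cls, shape: tuple[int, int], genotype: gt.Genotype) -> "Lattice":
        return cls(
            geno=np.full(shape, genotype.code, dtype=np.uint16),
            alive=np.ones(shape, dtype=bool),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.geno.shape

    @property
    def live_count(self) -> int:
        return int(self.alive.sum())

    def copy(self) -> "Lattice":
        return Lattice(self.geno.copy(), self.alive.copy())

    def genotype_at(self, row: int, col: int) -> gt.Genotype | None:
        if not self.alive[row, col]:
            return None
        return gt.Genotype.from_code(int(self.geno[row, col]))

    def class_grid(self) -> np.ndarray:
        """int8 grid of CellClass values; vacant sites are -1."""
        out = gt.class_lut()[self.geno].astype(np.int8)
        out[~self.alive] = -1
        return out


@dataclass(frozen=True)
class StepConfig:
    """All per-step parameters of the simulator."""

    p_death: float = 0.05
    immune_alpha: float = 0.1
    mutation_rate: float = 1e-5
    model: DiffusionModel = DiffusionModel.A
    fitness: FitnessParams = field(default_factory=FitnessParams)
    drug: DrugPolicy = NO_DRUG
    kernel_params: KernelParams = field(default_factory=KernelParams)

    def __post_init__(self) -> None:
        for name in ("p_death", "immune_alpha", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        object.__setattr__(self, "model", DiffusionModel(self.model))

    def build_kernels(self) -> dict[FactorId, Kernel]:
        return build_kernels(self.model, self.kernel_params)


@dataclass(frozen=True)
class StepMetrics:
    """Per-step summary over live cells."""

    step: int
    live_count: int
    normal: float
    cancer: float
    hypertumour: float
    partial_hypertumour: float
    other_mutant: float
    mutation_proportion: float

    def as_row(self) -> list[float]:
        return [getattr(self, c) for c in METRIC_COLUMNS]


class _StepTables:
    """Lookup tables derived from a StepConfig, built once per run."""

    def __init__(self, cfg: StepConfig):
        self.fitness = _FitnessTables(cfg.fitness)
        self.p_die = 1.0 - (1.0 - cfg.p_death) * (
            1.0 - gt.immune_probability_lut(cfg.immune_alpha)
        )
        self.cls = gt.class_lut()
        self.mutfrac = gt.mutated_fraction_lut()
        self.prod = {f: gt.locus_lut(name) for f, name in _PROD_LOCI.items()}


def producer_masks(lat: Lattice, tables: _StepTables | None = None) -> dict[FactorId, np.ndarray]:
    t = tables or _StepTables(StepConfig())
    return {f: t.prod[f][lat.geno] & lat.alive for f in FactorId}


def death_phase(
    lat: Lattice, cfg: StepConfig, rand: np.random.Generator,
    tables: _StepTables | None = None,
) -> Lattice:
    """Independent per-cell death: baseline turnover plus immune detection."""
    t = tables or _StepTables(cfg)
    u = rand.random(lat.shape)
    survived = lat.alive & ~(u < t.p_die[lat.geno])
    return Lattice(lat.geno, survived)


def birth_phase(
    lat: Lattice, fitness: np.ndarray, rand: np.random.Generator,
    floor: float = 1e-9,
) -> Lattice:
    """Fill vacancies from live von Neumann neighbours.

    Parent choice is proportional to neighbour fitness (from the supplied
    fitness grid, which corresponds to the step's pre-death configuration
    restricted to survivors); if every candidate's fitness is at the floor
    or below, the parent is uniform among live neighbours.  All parents are
    read from the pre-fill occupancy.
    """
    h, w = lat.shape
    vr, vc = np.nonzero(~lat.alive)
    if vr.size == 0:
        return lat.copy()
    # Neighbour weights, one column per direction (N, S, W, E).
    nbr_w = np.zeros((vr.size, 4))
    nbr_geno = np.zeros((vr.size, 4), dtype=np.uint16)
    nbr_alive = np.zeros((vr.size, 4), dtype=bool)
    live_f = np.where(lat.alive, np.nan_to_num(fitness, nan=0.0), 0.0)
    for j, (dr, dc) in enumerate(((-1, 0), (1, 0), (0, -1), (0, 1))):
        rr, cc = vr + dr, vc + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rri, cci = rr[ok], cc[ok]
        nbr_w[ok, j] = live_f[rri, cci]
        nbr_geno[ok, j] = lat.geno[rri, cci]
        nbr_alive[ok, j] = lat.alive[rri, cci]
    has_parent = nbr_alive.any(axis=1)
    if not has_parent.any():
        return lat.copy()
    # Uniform fallback where no candidate exceeds the fitness floor.
    degenerate = has_parent & (nbr_w.max(axis=1) <= floor)
    nbr_w[degenerate] = nbr_alive[degenerate].astype(float)

    idx = np.nonzero(has_parent)[0]
    cum = np.cumsum(nbr_w[idx], axis=1)
    draw = rand.random(idx.size) * cum[:, -1]
    choice = (draw[:, None] >= cum).sum(axis=1)

    new = lat.copy()
    new.geno[vr[idx], vc[idx]] = nbr_geno[idx, choice]
    new.alive[vr[idx], vc[idx]] = True
    return new


def mutation_phase(
    lat: Lattice, rate: float, rand: np.random.Generator
) -> Lattice:
    """One-way mutation of every live cell: each locus gains a mutation
    independently with probability ``rate`` (set bits never clear)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"mutation rate must be in [0, 1], got {rate}")
    new = lat.copy()
    if rate == 0.0 or not lat.alive.any():
        return new
    # Equivalent to an independent Bernoulli(rate) draw per (site, locus):
    # walk the flattened site x locus sequence with geometric gaps, so the
    # number of random draws scales with the number of mutation events.
    # Events on vacant sites are discarded (their genotypes are stale and
    # overwritten on rebirth), which leaves live-cell draws untouched.
    n = lat.geno.size * gt.N_LOCI
    flat_geno = new.geno.ravel()
    flat_alive = lat.alive.ravel()
    pos = int(rand.geometric(rate)) - 1
    while pos < n:
        site, locus = divmod(pos, gt.N_LOCI)
        if flat_alive[site]:
            flat_geno[site] |= np.uint16(1 << locus)
        pos += int(rand.geometric(rate))
    return new


def compute_metrics(
    lat: Lattice, step_index: int, tables: _StepTables | None = None
) -> StepMetrics:
    t = tables or _StepTables(StepConfig())
    live = lat.geno[lat.alive]
    n = live.size
    if n == 0:
        props = np.zeros(5)
        mut = 0.0
    else:
        props = np.bincount(t.cls[live], minlength=5) / n
        mut = float(t.mutfrac[live].mean())
    return StepMetrics(
        step=step_index,
        live_count=n,
        normal=float(props[gt.CellClass.NORMAL]),
        cancer=float(props[gt.CellClass.CANCER]),
        hypertumour=float(props[gt.CellClass.HYPERTUMOUR]),
        partial_hypertumour=float(props[gt.CellClass.PARTIAL_HYPERTUMOUR]),
        other_mutant=float(props[gt.CellClass.OTHER_MUTANT]),
        mutation_proportion=mut,
    )


def step(
    lat: Lattice,
    cfg: StepConfig,
    kernels: dict[FactorId, Kernel],
    rand: np.random.Generator,
    step_index: int = 0,
    tables: _StepTables | None = None,
    fields_engine: FieldComputer | None = None,
) -> tuple[Lattice, StepMetrics]:
    """One full simulation step; returns the new lattice and its metrics."""
    t = tables or _StepTables(cfg)
    masks = producer_masks(lat, t)
    if fields_engine is not None:
        fields = fields_engine.compute(masks)
    else:
        fields = compute_fields(masks, kernels)
    fit = fitness_map(lat, fields, cfg.fitness, cfg.drug, tables=t.fitness)
    lat = death_phase(lat, cfg, rand, tables=t)
    lat = birth_phase(lat, fit, rand, floor=cfg.fitness.floor)
    lat = mutation_phase(lat, cfg.mutation_rate, rand)
    return lat, compute_metrics(lat, step_index, t)


def run(
    initial: Lattice,
    cfg: StepConfig,
    n_steps: int,
    seed: int,
    return_final_lattice: bool = False,
):
    """Run ``n_steps`` full steps from ``initial``.

    Returns a DataFrame with one row per step (columns
    :data:`METRIC_COLUMNS`); deterministic given (initial, cfg, seed).
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rand = np.random.default_rng(seed)
    tables = _StepTables(cfg)
    kernels = cfg.build_kernels()
    engine = FieldComputer(kernels, initial.shape)
    lat = initial.copy()
    rows = np.empty((n_steps, len(METRIC_COLUMNS)))
    for i in range(n_steps):
        lat, m = step(lat, cfg, kernels, rand, step_index=i + 1, tables=tables,
                      fields_engine=engine)
        rows[i] = m.as_row()
    ts = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    ts["step"] = ts["step"].astype(int)
    ts["live_count"] = ts["live_count"].astype(int)
    if return_final_lattice:
        return ts, lat
    return ts
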