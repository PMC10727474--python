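"""Fitness of a cell from its genotype and the local factor concentrations.

The simulator assumes a linear benefit: a cell with the receptor for CGF *k*
gains ``A_k * r_k * g_k`` where ``g_k`` is the local concentration and
``r_k`` the drug multiplier (a CGF-targeting drug scales the received
concentration).  Producing a factor costs a fixed amount, lactate damages
non-resistant cells in proportion to its local concentration, and every
mutated locus carries a small burden so that mutated cells are less fit
unless compensated by growth-factor benefits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import genotype as gt
from .diffusion import FactorId, FieldSet

__all__ = [
    "FitnessParams",
    "DrugPolicy",
    "DRUG_GF12_HALF",
    "NO_DRUG",
    "cell_fitness",
    "fitness_map",
    "check_fitness_orderings",
]

_CGFS = (FactorId.GF1, FactorId.GF2, FactorId.GF3)


@dataclass(frozen=True)
class FitnessParams:
    """Fitness model parameters (arbitrary fitness units).

    w_base
        Baseline fitness of a wild-type cell in a factor-free environment.
    benefit_slope
        Linear benefit per unit concentration of CGF 1..3 (receptor needed).
    production_cost
        Cost of secreting CGF 1..3.
    lactate_production_cost
        Cost of the Warburg phenotype (secreting lactate).
    lactate_damage
        Damage per unit lactate concentration to non-resistant cells.
    mutation_penalty
        Burden per mutated locus.
    floor
        Lower clamp on fitness (kept tiny and positive so the
        fitness-proportional birth rule is always well defined).
    """

    w_base: float = 1.0
    benefit_slope: tuple[float, float, float] = (1.0, 1.0, 1.0)
    production_cost: tuple[float, float, float] = (0.3, 0.3, 0.3)
    lactate_production_cost: float = 0.05
    lactate_damage: float = 0.3
    mutation_penalty: float = 0.05
    floor: float = 1e-9

    def __post_init__(self) -> None:
        if not self.w_base > 0:
            raise ValueError(f"w_base must be positive, got {self.w_base}")
        for name in (
            "benefit_slope",
            "production_cost",
            "lactate_production_cost",
            "lactate_damage",
            "mutation_penalty",
            "floor",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if not (np.isfinite(v).all() and (v >= 0).all()):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass(frozen=True)
class DrugPolicy:
    """Multiplicative reduction of the received CGF concentrations.

    ``r[k] = 1`` means no drug against CGF k+1; the headline treatment halves
    the effect of CGFs 1 and 2 (:data:`DRUG_GF12_HALF`).
    """

    r: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for v in self.r:
            if not 0.0 < v <= 1.0:
                raise ValueError(f"drug multipliers must be in (0, 1], got {self.r}")


NO_DRUG = DrugPolicy()
DRUG_GF12_HALF = DrugPolicy(r=(0.5, 0.5, 1.0))


def cell_fitness(
    g: gt.Genotype,
    local: dict[FactorId, float],
    p: FitnessParams,
    drug: DrugPolicy = NO_DRUG,
) -> float:
    """Fitness of one cell given the factor concentrations at its site."""
    for f, v in local.items():
        if v < 0:
            raise ValueError(f"negative {f.value} concentration: {v}")
    w = p.w_base
    rec = (g.rec_gf1, g.rec_gf2, g.rec_gf3)
    prod = (g.prod_gf1, g.prod_gf2, g.prod_gf3)
    for k in range(3):
        if rec[k]:
            w += p.benefit_slope[k] * drug.r[k] * local.get(_CGFS[k], 0.0)
        if prod[k]:
            w -= p.production_cost[k]
    if g.prod_lactate:
        w -= p.lactate_production_cost
    if not g.lactate_resist:
        w -= p.lactate_damage * local.get(FactorId.LACTATE, 0.0)
    w -= p.mutation_penalty * sum(g.flags())
    return max(p.floor, w)


class _FitnessTables:
    """Per-genotype lookup tables so a whole lattice evaluates with a
    handful of vector operations."""

    def __init__(self, p: FitnessParams):
        n_mut = gt.mutated_fraction_lut() * gt.N_LOCI
        static = np.full(gt.N_GENOTYPES, p.w_base)
        for k, name in enumerate(("prod_gf1", "prod_gf2", "prod_gf3")):
            static -= gt.locus_lut(name) * p.production_cost[k]
        static -= gt.locus_lut("prod_lactate") * p.lactate_production_cost
        static -= p.mutation_penalty * n_mut
        self.static = static
        self.rec = [gt.locus_lut(f"rec_gf{k+1}").astype(float) for k in range(3)]
        self.vulnerable = (~gt.locus_lut("lactate_resist")).astype(float)


def fitness_map(
    lattice,
    fields: FieldSet,
    p: FitnessParams,
    drug: DrugPolicy = NO_DRUG,
    tables: _FitnessTables | None = None,
) -> np.ndarray:
    """Fitness grid for a whole lattice; vacant sites carry NaN.

    ``lattice`` is any object with ``geno`` (uint16 genotype codes) and
    ``alive`` (bool) grids of equal shape.
    """
    if lattice.geno.shape != fields.shape:
        raise ValueError(
            f"lattice shape {lattice.geno.shape} != field shape {fields.shape}"
        )
    t = tables or _FitnessTables(p)
    geno = lattice.geno
    w = t.static[geno].copy()
    for k in range(3):
        w += t.rec[k][geno] * (p.benefit_slope[k] * drug.r[k]) * fields[_CGFS[k]]
    w -= t.vulnerable[geno] * p.lactate_damage * fields[FactorId.LACTATE]
    np.maximum(w, p.floor, out=w)
    w[~lattice.alive] = np.nan
    return w


def check_fitness_orderings(
    p: FitnessParams, masses: dict[FactorId, float]
) -> None:
    """Startup self-check of the three qualitative orderings the model
    presumes, evaluated at cluster-interior concentrations (where the local
    concentration of each factor equals its kernel mass):

    1. full cancer beats normal tissue inside its own CGF/lactate cloud;
    2. a hypertumour beats full cancer at an identical local field;
    3. normal tissue beats an isolated hypertumour (no CGFs anywhere).

    Raises ``ValueError`` if the parameterisation violates any of them.
    """
    cancer = gt.make_archetype(gt.Archetype.CANCER_FULL)
    ht_w = gt.make_archetype(gt.Archetype.HT_WARBURG)
    ht_nw = gt.make_archetype(gt.Archetype.HT_NO_WARBURG)
    normal = gt.make_archetype(gt.Archetype.NORMAL)
    cloud = {f: masses[f] for f in FactorId}
    empty = {f: 0.0 for f in FactorId}
    f_cancer = cell_fitness(cancer, cloud, p)
    f_normal_in = cell_fitness(normal, cloud, p)
    f_normal_out = cell_fitness(normal, empty, p)
    if not f_cancer > f_normal_in:
        raise ValueError(
            f"cancer ({f_cancer:g}) does not beat normal ({f_normal_in:g}) "
            "inside its CGF cloud"
        )
    for ht in (ht_w, ht_nw):
        f_ht = cell_fitness(ht, cloud, p)
        if not f_ht > f_cancer:
            raise ValueError(
                f"hypertumour ({f_ht:g}) does not beat cancer ({f_cancer:g}) "
                "at equal field"
            )
        f_ht_iso = cell_fitness(ht, empty, p)
        if not f_normal_out > f_ht_iso:
            raise ValueError(
                f"normal ({f_normal_out:g}) does not beat isolated "
                f"hypertumour ({f_ht_iso:g})"
            )
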