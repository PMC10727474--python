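"""Genotypes, cell classes, one-way mutation and immune detection.

A cell's heritable state is nine boolean oncogene loci: production of the
three diffusible cancer growth factors (CGFs) and of lactate (the Warburg
effect), receptors for the three CGFs, resistance to lactate acidification,
and immune evasion.  A flag is ``True`` when the locus is mutated; mutation
is one-way (no reverse mutation), so a mutated locus never reverts.

Genotypes are also representable as 9-bit integer codes (bit *i* = locus *i*
in :data:`LOCI` order), which the lattice simulator uses for vectorised
lookup tables over all ``2**9 = 512`` genotypes.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LOCI",
    "N_LOCI",
    "Genotype",
    "CellClass",
    "Archetype",
    "classify",
    "mutate",
    "mutated_fraction",
    "immune_detection_probability",
    "make_archetype",
    "class_lut",
    "mutated_fraction_lut",
    "locus_lut",
    "immune_probability_lut",
]

#: Locus order used for bit codes and for 0/1 string serialisation.
LOCI = (
    "prod_gf1",
    "prod_gf2",
    "prod_gf3",
    "prod_lactate",
    "rec_gf1",
    "rec_gf2",
    "rec_gf3",
    "lactate_resist",
    "immune_evade",
)
N_LOCI = len(LOCI)
N_GENOTYPES = 1 << N_LOCI


class CellClass(enum.IntEnum):
    """Mutually exclusive, exhaustive phenotype classes.

    Classification depends only on CGF production and reception plus lactate
    resistance; Warburg status (``prod_lactate``) and immune evasion are
    orthogonal attributes and never affect the class.
    """

    NORMAL = 0
    CANCER = 1
    HYPERTUMOUR = 2
    PARTIAL_HYPERTUMOUR = 3
    OTHER_MUTANT = 4


class Archetype(enum.Enum):
    """Named genotypes used to build initial lattices."""

    NORMAL = "NORMAL"
    CANCER_FULL = "CANCER_FULL"
    HT_WARBURG = "HT_WARBURG"
    HT_NO_WARBURG = "HT_NO_WARBURG"


@dataclass(frozen=True)
class Genotype:
    prod_gf1: bool = False
    prod_gf2: bool = False
    prod_gf3: bool = False
    prod_lactate: bool = False
    rec_gf1: bool = False
    rec_gf2: bool = False
    rec_gf3: bool = False
    lactate_resist: bool = False
    immune_evade: bool = False

    def flags(self) -> tuple[bool, ...]:
        return tuple(bool(getattr(self, name)) for name in LOCI)

    @property
    def code(self) -> int:
        """9-bit integer code (bit i set iff locus i is mutated)."""
        return sum(1 << i for i, f in enumerate(self.flags()) if f)

    @classmethod
    def from_code(cls, code: int) -> "Genotype":
        if not 0 <= code < N_GENOTYPES:
            raise ValueError(f"genotype code out of range: {code}")
        return cls(**{name: bool(code >> i & 1) for i, name in enumerate(LOCI)})

    def to_string(self) -> str:
        """Serialise as a 9-character 0/1 string in locus order."""
        return "".join("1" if f else "0" for f in self.flags())

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        if len(s) != N_LOCI or set(s) - {"0", "1"}:
            raise ValueError(f"not a 9-character 0/1 genotype string: {s!r}")
        return cls(**{name: c == "1" for name, c in zip(LOCI, s)})


def classify(g: Genotype) -> CellClass:
    """Assign a genotype to its phenotype class.

    * NORMAL: every locus wild-type.
    * HYPERTUMOUR: produces no CGF, carries all three receptors and lactate
      resistance (the engineered defector phenotype).
    * PARTIAL_HYPERTUMOUR: produces no CGF and carries one or two receptors.
    * CANCER: produces all three CGFs and carries all three receptors
      ("full hallmarks" producer).
    * OTHER_MUTANT: everything else.
    """
    if not any(g.flags()):
        return CellClass.NORMAL
    produces = g.prod_gf1 or g.prod_gf2 or g.prod_gf3
    n_rec = int(g.rec_gf1) + int(g.rec_gf2) + int(g.rec_gf3)
    if not produces:
        if n_rec == 3 and g.lactate_resist:
            return CellClass.HYPERTUMOUR
        if n_rec in (1, 2):
            return CellClass.PARTIAL_HYPERTUMOUR
        return CellClass.OTHER_MUTANT
    if g.prod_gf1 and g.prod_gf2 and g.prod_gf3 and n_rec == 3:
        return CellClass.CANCER
    return CellClass.OTHER_MUTANT


def mutate(g: Genotype, per_locus_rate: float, rand: np.random.Generator) -> Genotype:
    """One round of one-way mutation: each wild-type locus flips on
    independently with probability ``per_locus_rate``; mutated loci are
    untouched (no reverse mutation)."""
    if not 0.0 <= per_locus_rate <= 1.0:
        raise ValueError(f"per_locus_rate must be in [0, 1], got {per_locus_rate}")
    draws = rand.random(N_LOCI) < per_locus_rate
    updates = {
        name: True
        for name, flag, hit in zip(LOCI, g.flags(), draws)
        if hit and not flag
    }
    return dataclasses.replace(g, **updates) if updates else g


def mutated_fraction(g: Genotype) -> float:
    """Fraction of the nine loci that are mutated."""
    return sum(g.flags()) / N_LOCI


def immune_detection_probability(g: Genotype, alpha: float) -> float:
    """Per-step probability of immune elimination.

    Linear in the mutated fraction with scale ``alpha``; immune evasion is
    absolute (probability 0).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if g.immune_evade:
        return 0.0
    return alpha * mutated_fraction(g)


def make_archetype(name: Archetype | str) -> Genotype:
    """Build a named archetype genotype.

    HT_WARBURG is the full-hallmark cancer genotype with CGF production
    knocked out (the engineered implant keeps every other hallmark,
    including lactate production); HT_NO_WARBURG additionally knocks out
    lactate production.
    """
    try:
        name = Archetype(name)
    except ValueError:
        raise ValueError(f"unknown archetype: {name!r}") from None
    if name is Archetype.NORMAL:
        return Genotype()
    full = Genotype(*([True] * N_LOCI))
    if name is Archetype.CANCER_FULL:
        return full
    ht = dataclasses.replace(full, prod_gf1=False, prod_gf2=False, prod_gf3=False)
    if name is Archetype.HT_WARBURG:
        return ht
    return dataclasses.replace(ht, prod_lactate=False)


# ---------------------------------------------------------------------------
# Lookup tables over all 512 genotype codes, for the vectorised simulator.

_ALL = [Genotype.from_code(c) for c in range(N_GENOTYPES)]


def class_lut() -> np.ndarray:
    """``(512,)`` int8 array: genotype code -> CellClass value."""
    return np.array([classify(g) for g in _ALL], dtype=np.int8)


def mutated_fraction_lut() -> np.ndarray:
    """``(512,)`` float array: genotype code -> mutated fraction."""
    return np.array([mutated_fraction(g) for g in _ALL])


def locus_lut(name: str) -> np.ndarray:
    """``(512,)`` bool array: genotype code -> state of one locus."""
    i = LOCI.index(name)
    return np.array([bool(c >> i & 1) for c in range(N_GENOTYPES)])


def immune_probability_lut(alpha: float) -> np.ndarray:
    """``(512,)`` float array of immune detection probabilities."""
    return np.array([immune_detection_probability(g, alpha) for g in _ALL])
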