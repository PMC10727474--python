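"""Initial geometries, scenario matrix, replicate ensembles and the
0.5-threshold conditional analysis.

The reference layout is a 100 x 100 field of normal tissue carrying a
centred 22 x 22 cluster of full-hallmark cancer cells whose centre holds a
12 x 7 implant: normal cells (control), engineered hypertumours with the
Warburg effect, or hypertumours without it.  Each scenario crosses an
implant type with a drug state (the drug halves the effect of CGFs 1 and 2)
and a diffusion model, and is replicated with consecutive seeds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genotype as gt
from .diffusion import DiffusionModel
from .dynamics import Lattice, METRIC_COLUMNS, StepConfig, run
from .fitness import DRUG_GF12_HALF, NO_DRUG

__all__ = [
    "CentreFill",
    "GeometryConfig",
    "Scenario",
    "EnsembleResult",
    "make_initial",
    "run_ensemble",
    "split_by_final_proportion",
    "scenario_matrix",
]


class CentreFill(enum.Enum):
    NORMAL_CONTROL = "NORMAL_CONTROL"
    HT_WARBURG = "HT_WARBURG"
    HT_NO_WARBURG = "HT_NO_WARBURG"


_FILL_ARCHETYPE = {
    CentreFill.NORMAL_CONTROL: gt.Archetype.NORMAL,
    CentreFill.HT_WARBURG: gt.Archetype.HT_WARBURG,
    CentreFill.HT_NO_WARBURG: gt.Archetype.HT_NO_WARBURG,
}


@dataclass(frozen=True)
class GeometryConfig:
    """Field, cancer-ring and implant dimensions (cells).

    The ring is the ``ring_h x ring_w`` block minus the ``hole_h x hole_w``
    hole.  Blocks are centred; where a margin is odd the extra row/column
    goes to the bottom/right.
    """

    height: int = 100
    width: int = 100
    ring_h: int = 22
    ring_w: int = 22
    hole_h: int = 7
    hole_w: int = 12

    def __post_init__(self) -> None:
        if min(self.height, self.width, self.ring_h, self.ring_w, self.hole_h, self.hole_w) <= 0:
            raise ValueError("all geometry dimensions must be positive")
        if self.ring_h > self.height or self.ring_w > self.width:
            raise ValueError("cancer ring does not fit in the field")
        if self.hole_h > self.ring_h or self.hole_w > self.ring_w:
            raise ValueError("implant hole larger than the cancer ring")

    def ring_slices(self) -> tuple[slice, slice]:
        r0 = (self.height - self.ring_h) // 2
        c0 = (self.width - self.ring_w) // 2
        return slice(r0, r0 + self.ring_h), slice(c0, c0 + self.ring_w)

    def hole_slices(self) -> tuple[slice, slice]:
        r0 = (self.height - self.hole_h) // 2
        c0 = (self.width - self.hole_w) // 2
        return slice(r0, r0 + self.hole_h), slice(c0, c0 + self.hole_w)


@dataclass(frozen=True)
class Scenario:
    centre_fill: CentreFill = CentreFill.HT_NO_WARBURG
    drug_on: bool = False
    model: DiffusionModel = DiffusionModel.A
    n_steps: int = 10_000
    n_replicates: int = 500
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        object.__setattr__(self, "centre_fill", CentreFill(self.centre_fill))
        object.__setattr__(self, "model", DiffusionModel(self.model))


def make_initial(
    scenario: Scenario, geometry: GeometryConfig | None = None
) -> Lattice:
    """Build the initial lattice for a scenario."""
    geo = geometry or GeometryConfig()
    lat = Lattice.full((geo.height, geo.width), gt.make_archetype(gt.Archetype.NORMAL))
    rs, cs = geo.ring_slices()
    lat.geno[rs, cs] = gt.make_archetype(gt.Archetype.CANCER_FULL).code
    hr, hc = geo.hole_slices()
    lat.geno[hr, hc] = gt.make_archetype(_FILL_ARCHETYPE[scenario.centre_fill]).code
    return lat


@dataclass
class EnsembleResult:
    """Replicate aggregate: per-step mean/sd and per-replicate finals."""

    scenario: Scenario
    mean: pd.DataFrame
    sd: pd.DataFrame
    finals: pd.DataFrame  # one row per replicate, METRIC_COLUMNS + replicate/seed
    replicates: list[pd.DataFrame] = field(default_factory=list)
    empty: bool = False

    @property
    def n_replicates(self) -> int:
        return len(self.finals)


_VALUE_COLUMNS = [c for c in METRIC_COLUMNS if c != "step"]


def _aggregate(scenario: Scenario, runs: list[pd.DataFrame], finals: pd.DataFrame,
               keep_replicates: bool) -> EnsembleResult:
    if not runs:
        empty = pd.DataFrame(columns=METRIC_COLUMNS)
        return EnsembleResult(scenario, empty, empty.copy(), finals, [], empty=True)
    stack = np.stack([r[_VALUE_COLUMNS].to_numpy() for r in runs])
    steps = runs[0]["step"]
    mean = pd.DataFrame(stack.mean(axis=0), columns=_VALUE_COLUMNS)
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), columns=_VALUE_COLUMNS)
    mean.insert(0, "step", steps)
    sd.insert(0, "step", steps)
    return EnsembleResult(
        scenario, mean, sd, finals.reset_index(drop=True),
        runs if keep_replicates else [],
    )


def run_ensemble(
    scenario: Scenario,
    cfg: StepConfig | None = None,
    geometry: GeometryConfig | None = None,
    keep_replicates: bool = True,
) -> EnsembleResult:
    """Run ``n_replicates`` independent runs (replicate *i* uses seed
    ``base_seed + i``) and aggregate.

    The scenario's drug state overrides ``cfg.drug``: on means the policy
    that halves the received CGF 1 and 2 concentrations, off means no drug.
    """
    cfg = cfg or StepConfig(model=scenario.model)
    cfg = replace(
        cfg,
        model=scenario.model,
        drug=DRUG_GF12_HALF if scenario.drug_on else NO_DRUG,
    )
    initial = make_initial(scenario, geometry)
    runs, final_rows = [], []
    for i in range(scenario.n_replicates):
        seed = scenario.base_seed + i
        ts = run(initial, cfg, scenario.n_steps, seed)
        runs.append(ts)
        row = ts.iloc[-1].to_dict()
        row.update(replicate=i, seed=seed)
        final_rows.append(row)
    finals = pd.DataFrame(final_rows)
    return _aggregate(scenario, runs, finals, keep_replicates)


def split_by_final_proportion(
    ens: EnsembleResult, threshold: float = 0.5
) -> tuple[EnsembleResult, EnsembleResult]:
    """Partition replicates by their final (partial) hypertumour proportion.

    The split statistic is the final-step ``hypertumour +
    partial_hypertumour`` proportion; replicates at or above the threshold
    go to the first group.  Requires per-replicate series
    (``keep_replicates=True``).  An empty group is flagged via ``empty``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if ens.n_replicates and not ens.replicates:
        raise ValueError("per-replicate series were not retained; "
                         "rerun with keep_replicates=True")
    final_ht = (ens.finals["hypertumour"] + ens.finals["partial_hypertumour"]).to_numpy()
    above = final_ht >= threshold
    groups = []
    for mask in (above, ~above):
        runs = [r for r, m in zip(ens.replicates, mask) if m]
        groups.append(_aggregate(ens.scenario, runs, ens.finals[mask], True))
    return groups[0], groups[1]


def scenario_matrix(
    model: DiffusionModel | str,
    n_replicates: int = 500,
    base_seed: int = 0,
) -> list[Scenario]:
    """The six scenarios of one diffusion model: three centre fills crossed
    with drug on/off.  Runs last 10 000 steps, except Model B without the
    drug, which needs 30 000 steps to reach its finalized configuration."""
    model = DiffusionModel(model)
    out = []
    for fill in CentreFill:
        for drug_on in (False, True):
            n_steps = 10_000
            if model is DiffusionModel.B and not drug_on:
                n_steps = 30_000
            out.append(
                Scenario(
                    centre_fill=fill,
                    drug_on=drug_on,
                    model=model,
                    n_steps=n_steps,
                    n_replicates=n_replicates,
                    base_seed=base_seed,
                )
            )
    return out
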