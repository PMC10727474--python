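"""Diffusion kernels and concentration fields for the secreted factors.

Each diffusible factor (three CGFs and lactate) spreads from every producing
cell according to a fixed kernel; a step's concentration field is the
discrete convolution of the producer-occupancy mask with that kernel.
Fields are instantaneous maps of the current occupancy — there is no
temporal accumulation or decay.

Tissue permeability is modelled by three kernel variants: Model B (short
range), A (intermediate) and C (long range).  Widening the range rescales
the kernel so the total mass within the diffusion range is conserved per
factor across models: higher permeability means a larger radius but a lower
average concentration.
"""

from __future__ import annotations

import enum
import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FactorId",
    "DiffusionModel",
    "KernelParams",
    "Kernel",
    "FieldSet",
    "FieldComputer",
    "build_kernel",
    "build_kernels",
    "compute_fields",
]


class FactorId(enum.Enum):
    GF1 = "GF1"
    GF2 = "GF2"
    GF3 = "GF3"
    LACTATE = "LACTATE"


class DiffusionModel(enum.Enum):
    """Tissue-permeability variants ordered by range: B < A < C."""

    A = "A"
    B = "B"
    C = "C"


@dataclass(frozen=True)
class KernelParams:
    """Kernel configuration.

    base_radius
        Per-factor radius (cells) at Model A scale.  GF1 < GF2 < GF3 so that
        growth factor 1 has the shortest and growth factor 3 the longest
        diffusion range; lactate sits between GF1 and GF2.
    mass
        Per-factor total kernel mass (conserved across models).
    model_scale
        Radius multiplier per model, B < A < C.
    flat
        If true, weights are uniform over the square support (otherwise a
        truncated exponential decay with length radius/2).
    """

    base_radius: dict[FactorId, float] = field(
        default_factory=lambda: {
            FactorId.GF1: 2.0,
            FactorId.GF2: 4.0,
            FactorId.GF3: 6.0,
            FactorId.LACTATE: 3.0,
        }
    )
    mass: dict[FactorId, float] = field(
        default_factory=lambda: {
            FactorId.GF1: 1.0,
            FactorId.GF2: 1.0,
            FactorId.GF3: 1.0,
            FactorId.LACTATE: 3.0,
        }
    )
    model_scale: dict[DiffusionModel, float] = field(
        default_factory=lambda: {
            DiffusionModel.B: 0.5,
            DiffusionModel.A: 1.0,
            DiffusionModel.C: 2.0,
        }
    )
    flat: bool = False

    def __post_init__(self) -> None:
        scales = self.model_scale
        if not scales[DiffusionModel.B] < scales[DiffusionModel.A] < scales[DiffusionModel.C]:
            raise ValueError("model scales must satisfy scale(B) < scale(A) < scale(C)")
        for f, r in self.base_radius.items():
            if r <= 0:
                raise ValueError(f"base radius for {f.value} must be positive, got {r}")
        for f, m in self.mass.items():
            if m <= 0:
                raise ValueError(f"kernel mass for {f.value} must be positive, got {m}")


@dataclass(frozen=True)
class Kernel:
    """A factor's diffusion footprint: a (2r+1) x (2r+1) non-negative weight
    array whose sum equals the factor's configured mass exactly."""

    factor: FactorId
    model: DiffusionModel
    radius: int
    weights: np.ndarray

    @property
    def mass(self) -> float:
        return float(self.weights.sum())

    def save(self, path_prefix: str | pathlib.Path) -> None:
        """Export as CSV plus a JSON side-car with the metadata."""
        prefix = pathlib.Path(path_prefix)
        np.savetxt(prefix.with_suffix(".csv"), self.weights, delimiter=",")
        meta = {
            "factor": self.factor.value,
            "model": self.model.value,
            "radius": self.radius,
            "mass": self.mass,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def build_kernel(
    factor: FactorId,
    model: DiffusionModel | str,
    params: KernelParams | None = None,
) -> Kernel:
    """Construct one factor's kernel for one model.

    The radius is ``round(base_radius * scale(model))`` (minimum 1).  Weights
    decay as ``exp(-d / (radius/2))`` with *d* the Euclidean offset length,
    over the full square support of side ``2*radius + 1``, then rescale so
    their sum equals the factor's mass.  With ``flat=True`` the weights are
    uniform.
    """
    params = params or KernelParams()
    model = DiffusionModel(model)
    radius = max(1, int(math.floor(params.base_radius[factor] * params.model_scale[model] + 0.5)))
    offs = np.arange(-radius, radius + 1)
    dist = np.hypot(offs[:, None], offs[None, :])
    if params.flat:
        w = np.ones_like(dist)
    else:
        w = np.exp(-dist / (radius / 2.0))
    w *= params.mass[factor] / w.sum()
    return Kernel(factor=factor, model=model, radius=radius, weights=w)


def build_kernels(
    model: DiffusionModel | str, params: KernelParams | None = None
) -> dict[FactorId, Kernel]:
    """Kernels for all four factors under one model."""
    params = params or KernelParams()
    return {f: build_kernel(f, model, params) for f in FactorId}


@dataclass
class FieldSet:
    """One concentration grid per factor, shaped like the lattice."""

    grids: dict[FactorId, np.ndarray]

    def __getitem__(self, factor: FactorId) -> np.ndarray:
        return self.grids[factor]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.grids.values())).shape

    def save(self, path_prefix: str | pathlib.Path) -> None:
        prefix = pathlib.Path(path_prefix)
        for f, grid in self.grids.items():
            np.savetxt(f"{prefix}_{f.value.lower()}.csv", grid, delimiter=",")


class FieldComputer:
    """FFT convolution engine with per-factor kernel spectra precomputed
    for a fixed lattice shape (the step loop reuses one instance)."""

    def __init__(self, kernels: dict[FactorId, Kernel], shape: tuple[int, int]):
        from scipy import fft as sp_fft

        self.shape = shape
        self._plans = {}
        for f, k in kernels.items():
            full = (shape[0] + 2 * k.radius, shape[1] + 2 * k.radius)
            fshape = tuple(sp_fft.next_fast_len(n, True) for n in full)
            self._plans[f] = (
                k.radius,
                fshape,
                sp_fft.rfftn(k.weights, fshape),
            )

    def compute(self, producer_masks: dict[FactorId, np.ndarray]) -> FieldSet:
        from scipy import fft as sp_fft

        shapes = {m.shape for m in producer_masks.values()}
        if shapes != {self.shape}:
            raise ValueError(
                f"producer masks must have shape {self.shape}, got {sorted(shapes)}"
            )
        h, w = self.shape
        grids: dict[FactorId, np.ndarray] = {}
        for f, mask in producer_masks.items():
            if not mask.any():
                grids[f] = np.zeros(self.shape)
                continue
            radius, fshape, k_hat = self._plans[f]
            m_hat = sp_fft.rfftn(mask.astype(float), fshape)
            full = sp_fft.irfftn(m_hat * k_hat, fshape)
            out = full[radius:radius + h, radius:radius + w].copy()
            # FFT convolution can leave O(1e-15) negative dust; clamp it.
            np.maximum(out, 0.0, out=out)
            grids[f] = out
        return FieldSet(grids)


def compute_fields(
    producer_masks: dict[FactorId, np.ndarray],
    kernels: dict[FactorId, Kernel],
) -> FieldSet:
    """Convolve each factor's producer mask with its kernel.

    Grid edges are absorbing: kernel mass falling outside the lattice is
    lost (no wrap-around).
    """
    shapes = {m.shape for m in producer_masks.values()}
    if len(shapes) != 1:
        raise ValueError(f"producer masks disagree in shape: {sorted(shapes)}")
    return FieldComputer(kernels, shapes.pop()).compute(producer_masks)
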