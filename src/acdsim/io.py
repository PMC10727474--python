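"""File output: time-series CSVs, lattice snapshots and run metadata.

Everything is plain CSV/JSON — the grids are small (100 x 100) and
inspectability beats compactness.
"""

from __future__ import annotations

import json
import pathlib
import time

import numpy as np
import pandas as pd

from .diffusion import FieldSet
from .dynamics import Lattice, METRIC_COLUMNS
from .experiments import EnsembleResult
from .genotype import Genotype, N_LOCI

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "snapshot",
    "read_class_grid",
    "read_genotype_grid",
    "write_metadata",
    "VACANT_CLASS_CODE",
    "VACANT_GENOTYPE_TOKEN",
]

#: Class-grid code for a vacant site (CellClass values are 0..4).
VACANT_CLASS_CODE = -1
#: Genotype-grid token for a vacant site (never a 0/1 string).
VACANT_GENOTYPE_TOKEN = "." * N_LOCI

_VALUE_COLUMNS = [c for c in METRIC_COLUMNS if c != "step"]


def write_timeseries(ts: pd.DataFrame | EnsembleResult, path: str | pathlib.Path) -> None:
    """Write a run's time series (one row per step) or an ensemble
    aggregate (mean and sd columns per metric) as CSV at full precision."""
    if isinstance(ts, EnsembleResult):
        if ts.empty or len(ts.mean) == 0:
            raise ValueError("refusing to write an empty ensemble")
        out = pd.DataFrame({"step": ts.mean["step"]})
        for c in _VALUE_COLUMNS:
            out[f"{c}_mean"] = ts.mean[c]
            out[f"{c}_sd"] = ts.sd[c]
    else:
        if len(ts) == 0:
            raise ValueError("refusing to write an empty time series")
        out = ts[METRIC_COLUMNS]
    out.to_csv(path, index=False)


def read_timeseries(path: str | pathlib.Path) -> pd.DataFrame:
    return pd.read_csv(path)


def snapshot(
    lat: Lattice,
    fitness_grid: np.ndarray | None,
    fields: FieldSet | None,
    path_prefix: str | pathlib.Path,
) -> list[pathlib.Path]:
    """Export a configuration for external rendering.

    Writes ``<prefix>_classes.csv`` (CellClass codes, vacancy -1),
    ``<prefix>_genotypes.csv`` (9-character 0/1 strings, vacancy '.'*9),
    and, when given, ``<prefix>_fitness.csv`` (NaN at vacancies) and one
    ``<prefix>_<factor>.csv`` per concentration field.
    """
    if fitness_grid is not None and fitness_grid.shape != lat.shape:
        raise ValueError("fitness grid shape does not match the lattice")
    if fields is not None and fields.shape != lat.shape:
        raise ValueError("field shapes do not match the lattice")
    prefix = pathlib.Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []

    p = pathlib.Path(f"{prefix}_classes.csv")
    np.savetxt(p, lat.class_grid(), fmt="%d", delimiter=",")
    written.append(p)

    strings = np.array(
        [Genotype.from_code(c).to_string() for c in range(512)], dtype=object
    )[lat.geno]
    strings[~lat.alive] = VACANT_GENOTYPE_TOKEN
    p = pathlib.Path(f"{prefix}_genotypes.csv")
    pd.DataFrame(strings).to_csv(p, index=False, header=False)
    written.append(p)

    if fitness_grid is not None:
        p = pathlib.Path(f"{prefix}_fitness.csv")
        np.savetxt(p, fitness_grid, delimiter=",")
        written.append(p)
    if fields is not None:
        fields.save(prefix)
        written.extend(
            pathlib.Path(f"{prefix}_{f.value.lower()}.csv") for f in fields.grids
        )
    return written


def read_class_grid(path: str | pathlib.Path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, delimiter=",")


def read_genotype_grid(path: str | pathlib.Path) -> np.ndarray:
    """Read back a genotype-string grid (object array of 9-char tokens)."""
    return pd.read_csv(path, header=None, dtype=str).to_numpy()


def write_metadata(
    path: str | pathlib.Path,
    resolved_config: dict,
    seed: int,
    **extra,
) -> None:
    """Run metadata: the fully-resolved config (every default made
    explicit), the seed, a timestamp and any extra fields (durations,
    replicate counts, ...)."""
    meta = {
        "seed": seed,
        "config": resolved_config,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }
    pathlib.Path(path).write_text(json.dumps(meta, indent=2, default=str))
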