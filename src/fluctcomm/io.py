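"""Trajectory and table import/export.

Trajectories are stored as delimited text (one row per recorded time, first
column ``time``, remaining columns the species, header row = species ids)
plus a JSON sidecar of parameters and seed.  Fitness matrices go to a second
file with suffix ``.fitness.tsv``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .community import CommunityParams, Trajectory
from .errors import ParameterError
from .fitness import NoiseParams

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "save_trajectory",
    "load_trajectory",
    "read_abundance_table",
]


def params_to_dict(params: CommunityParams) -> dict:
    d = dataclasses.asdict(params)
    noise = d.pop("noise")
    for key in ("mean_fitness", "phases"):
        if isinstance(noise.get(key), np.ndarray):
            noise[key] = noise[key].tolist()
    d["noise"] = noise
    return d


def params_from_dict(d: dict) -> CommunityParams:
    d = dict(d)
    noise = dict(d.pop("noise"))
    for key in ("mean_fitness", "phases"):
        if isinstance(noise.get(key), list):
            noise[key] = np.asarray(noise[key], dtype=float)
    return CommunityParams(noise=NoiseParams(**noise), **d)


def save_trajectory(traj: Trajectory, path, fitness: bool = True) -> Path:
    """Write a trajectory as TSV (+ ``.fitness.tsv``) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    species = [f"sp{j}" for j in range(traj.abundance.shape[1])]
    df = pd.DataFrame(traj.abundance, columns=species)
    df.insert(0, "time", traj.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if fitness:
        dff = pd.DataFrame(traj.fitness, columns=species)
        dff.insert(0, "time", traj.times)
        dff.to_csv(path.with_suffix(path.suffix + ".fitness.tsv"), sep="\t",
                   index=False, float_format="%.10g")
    sidecar = {
        "params": params_to_dict(traj.params),
        "seed": traj.seed,
        "n_times": int(len(traj.times)),
        "has_fitness": bool(fitness),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=float)
    )
    return path


def load_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`save_trajectory`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "time" not in df.columns:
        raise ParameterError(f"{path} has no 'time' column")
    times = df["time"].to_numpy(float)
    abundance = df.drop(columns="time").to_numpy(float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ParameterError(f"missing parameter sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    params = params_from_dict(sidecar["params"])
    fit_path = path.with_suffix(path.suffix + ".fitness.tsv")
    if sidecar.get("has_fitness") and fit_path.exists():
        fitness = pd.read_csv(fit_path, sep="\t").drop(columns="time").to_numpy(float)
    else:
        fitness = np.full_like(abundance, np.nan)
    return Trajectory(times, abundance, fitness, params, sidecar.get("seed"))


def read_abundance_table(path, delimiter: Optional[str] = None) -> np.ndarray:
    """Read a one-column abundance list or a times x species table.

    Accepts whitespace-, tab-, comma- or semicolon-delimited text with an
    optional header row; a ``time`` column, if present, is discarded.
    Returns a flat array of the remaining values (the statistics layer pools
    whatever it gets).
    """
    import re

    split = re.compile(r"[,\t;\s]+") if delimiter is None else re.compile(
        re.escape(delimiter))
    header = None
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = [t for t in split.split(line) if t]
        try:
            rows.append([float(t) for t in tokens])
        except ValueError:
            if header is None and not rows:
                header = tokens
            else:
                raise ParameterError(f"non-numeric row in {path}: {line!r}")
    if not rows:
        raise ParameterError(f"no data rows in {path}")
    drop = None
    if header is not None:
        lowered = [h.lower() for h in header]
        if "time" in lowered:
            drop = lowered.index("time")
    return np.concatenate([
        np.asarray([v for j, v in enumerate(r) if j != drop], dtype=float)
        for r in rows
    ])
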