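"""File formats: XYZ trajectories, JSONL frame records, CSV summaries, and
YAML run configurations."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .guiding import GuidingParams, Mode
from .integrators import IntegratorConfig
from .replica import StageSpec
from .systems import (
    LJParams,
    SDWParams,
    SystemSpec,
    build_argon_system,
    build_harmonic_system,
    build_sdw_system,
)

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_frames_jsonl",
    "read_frames_jsonl",
    "load_config",
    "RunSetup",
]


def write_xyz(
    path, positions: np.ndarray, element: str = "Ar", comment: str = ""
) -> None:
    """Write frames (n_frames, n_atoms, 3) as a multi-frame XYZ file."""
    r = np.asarray(positions, dtype=float)
    if r.ndim == 2:
        r = r[None]
    with open(path, "w") as fh:
        for k, frame in enumerate(r):
            fh.write(f"{frame.shape[0]}\n{comment} frame {k}\n")
            for x, y, z in frame:
                fh.write(f"{element} {x:.10f} {y:.10f} {z:.10f}\n")


def read_xyz(path) -> np.ndarray:
    """Read a multi-frame XYZ file into (n_frames, n_atoms, 3)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.array(frames)


def write_frames_jsonl(path, frames: pd.DataFrame) -> None:
    """One JSON object per frame, keys = column names."""
    with open(path, "w") as fh:
        for row in frames.to_dict(orient="records"):
            fh.write(json.dumps(row, allow_nan=True) + "\n")


def read_frames_jsonl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    return pd.DataFrame(rows)


class RunSetup:
    """A fully resolved run: system, initial conditions, integrator config,
    and (optionally) a stage ladder."""

    def __init__(self, system, positions, velocities, cfg, stages, out_dir):
        self.system = system
        self.positions = positions
        self.velocities = velocities
        self.cfg = cfg
        self.stages = stages
        self.out_dir = out_dir


def _require(section: dict, key: str, where: str):
    if key not in section:
        raise ConfigurationError(f"missing key {key!r} in section '{where}'")
    return section[key]


def load_config(path, overrides: dict | None = None) -> RunSetup:
    """Parse and validate a YAML run configuration.

    Sections: ``system`` (kind: sdw | argon | harmonic, plus parameters),
    ``integrator`` (dt, n_steps, temperature, seed, record_every,
    traj_every), ``guiding`` (mode, t_L, t_avg, lambda, mu, gamma),
    optional ``stages`` (list of {T, lambda, mu}) and ``output`` (dir).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    for key, val in (overrides or {}).items():
        sect, _, name = key.partition(".")
        raw.setdefault(sect, {})[name] = val

    sys_sec = raw.get("system")
    if not isinstance(sys_sec, dict):
        raise ConfigurationError(f"{path}: missing or malformed 'system' section")
    kind = _require(sys_sec, "kind", "system")
    gd = raw.get("guiding", {}) or {}
    it = raw.get("integrator", {}) or {}
    try:
        guiding = GuidingParams(
            t_L=float(gd.get("t_L", 0.2)),
            t_avg=float(gd["t_avg"]) if "t_avg" in gd else None,
            lambda_=float(gd.get("lambda", 0.0)),
            mu=float(gd.get("mu", 0.0)),
            gamma=float(gd.get("gamma", 0.0)),
            mode=Mode(gd.get("mode", "MD")),
        )
    except ValueError as exc:
        raise ConfigurationError(f"{path}: guiding: {exc}") from exc
    cfg = IntegratorConfig(
        dt=float(it.get("dt", 0.001)),
        n_steps=int(it.get("n_steps", 1000)),
        temperature=float(it.get("temperature", 300.0)),
        guiding=guiding,
        seed=int(it.get("seed", 0)),
        record_every=int(it.get("record_every", 10)),
        traj_every=int(it.get("traj_every", 0)),
    )

    velocities = None
    if kind == "sdw":
        params = SDWParams(
            a=float(sys_sec.get("a", 1.0)),
            b=float(sys_sec.get("b", 0.25)),
            c=float(sys_sec.get("c", 1000.0)),
            y0=float(sys_sec.get("y0", 1.0)),
        )
        system, positions = build_sdw_system(
            params, mass=float(sys_sec.get("mass", 39.948))
        )
    elif kind == "argon":
        system, positions, velocities = build_argon_system(
            n_atoms=int(sys_sec.get("n_atoms", 125)),
            box_edge=(float(sys_sec["box"]) if "box" in sys_sec else None),
            temperature=cfg.temperature,
            seed=cfg.seed,
            cutoff=(float(sys_sec["cutoff"]) if "cutoff" in sys_sec else None),
        )
    elif kind == "harmonic":
        system, positions = build_harmonic_system(
            k_spring=float(sys_sec.get("k_spring", 1.0)),
            n_atoms=int(sys_sec.get("n_atoms", 1)),
            mass=float(sys_sec.get("mass", 39.948)),
        )
    else:
        raise ConfigurationError(
            f"{path}: system.kind must be sdw|argon|harmonic, got {kind!r}"
        )

    stages = None
    if "stages" in raw and raw["stages"]:
        stages = [
            StageSpec(
                index=i,
                T=float(_require(s, "T", f"stages[{i}]")),
                lambda_=float(s.get("lambda", 0.0)),
                mu=float(s.get("mu", 0.0)),
            )
            for i, s in enumerate(raw["stages"])
        ]
    out_dir = Path((raw.get("output", {}) or {}).get("dir", "sgsim_out"))
    return RunSetup(system, positions, velocities, cfg, stages, out_dir)
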