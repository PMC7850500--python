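"""Run configuration: flat key-value files tying the modules together.

Configs are flat YAML (or JSON, a YAML subset) mappings whose keys are the
standard parameter symbols (D_a, v_a, k_d, omega, omega_d, alpha, n_tot,
L, N_g, D_psi, kappa, epsilon, beta, A_0) plus run controls (seed, tol,
t_end, snapshot_dt, noise_amp, dim, out).  Unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grids import DomainGrid
from .params import ModelParams, PhaseFieldParams

_MODEL_KEYS = ("D_a", "D_i", "v_a", "k_d", "omega0", "omega", "omega_d",
               "alpha", "n_tot")
_PF_KEYS = ("D_psi", "kappa", "epsilon", "beta", "A_0")
_GRID_KEYS = ("L", "N_g", "dim")
_RUN_KEYS = ("seed", "tol", "t_end", "snapshot_dt", "noise_amp", "out")


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of model, phase-field, grid and run settings."""

    model: ModelParams = field(default_factory=ModelParams)
    phase_field: PhaseFieldParams = field(default_factory=PhaseFieldParams)
    grid: DomainGrid = field(default_factory=lambda: DomainGrid(
        L=1.3, N_g=128, dim=2))
    seed: int = 0
    tol: float = 1e-6
    t_end: float = 1.0
    snapshot_dt: float = 0.05
    noise_amp: float | None = None
    out: str | None = None

    def to_dict(self) -> dict:
        d = {}
        d.update(self.model.to_dict())
        d.update(self.phase_field.to_dict())
        d.update({"L": self.grid.L, "N_g": self.grid.N_g,
                  "dim": self.grid.dim})
        d.update({"seed": self.seed, "tol": self.tol, "t_end": self.t_end,
                  "snapshot_dt": self.snapshot_dt})
        if self.noise_amp is not None:
            d["noise_amp"] = self.noise_amp
        if self.out is not None:
            d["out"] = self.out
        return d


def config_from_dict(data: dict) -> RunConfig:
    """Build a validated RunConfig; unknown keys raise ValueError."""
    known = set(_MODEL_KEYS) | set(_PF_KEYS) | set(_GRID_KEYS) \
        | set(_RUN_KEYS)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                         f"known keys are {sorted(known)}")
    model = ModelParams(**{k: float(data[k]) for k in _MODEL_KEYS
                           if k in data})
    pf = PhaseFieldParams(**{k: float(data[k]) for k in _PF_KEYS
                             if k in data})
    grid_kwargs = {"L": 1.3, "N_g": 128, "dim": 2}
    for k in _GRID_KEYS:
        if k in data:
            grid_kwargs[k] = type(grid_kwargs[k])(data[k])
    grid = DomainGrid(**grid_kwargs)
    run = {}
    for k in _RUN_KEYS:
        if k in data:
            run[k] = data[k]
    if "seed" in run:
        run["seed"] = int(run["seed"])
    for k in ("tol", "t_end", "snapshot_dt", "noise_amp"):
        if k in run and run[k] is not None:
            run[k] = float(run[k])
    return RunConfig(model=model, phase_field=pf, grid=grid, **run)


def load_config(path) -> RunConfig:
    """Read and validate a YAML/JSON config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got "
                         f"{type(data).__name__}")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    """Write a config as flat YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
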