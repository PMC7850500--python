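"""HDF5 snapshot storage and CSV table export."""

from __future__ import annotations

import json

import h5py
import pandas as pd

from .dynamics import FieldState, SimResult
from .grids import DomainGrid
from .params import ModelParams


def save_snapshots(path, result: SimResult) -> None:
    """Write a SimResult to HDF5: one group per snapshot (fields as
    datasets), params/grid/seed as root attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["params"] = json.dumps(result.params.to_dict())
        f.attrs["L"] = result.grid.L
        f.attrs["N_g"] = result.grid.N_g
        f.attrs["dim"] = result.grid.dim
        f.attrs["seed"] = -1 if result.seed is None else result.seed
        f.attrs["n_accepted"] = result.n_accepted
        f.attrs["n_rejected"] = result.n_rejected
        f.create_dataset("dt_history", data=result.dt_history)
        for i, s in enumerate(result.snapshots):
            g = f.create_group(f"snap{i:06d}")
            g.attrs["t"] = s.t
            g.create_dataset("c", data=s.c)
            g.create_dataset("p_x", data=s.p_x)
            if s.p_y is not None:
                g.create_dataset("p_y", data=s.p_y)
            g.create_dataset("n_a", data=s.n_a)
            g.create_dataset("n_i", data=s.n_i)


def load_snapshots(path) -> SimResult:
    """Read a SimResult written by :func:`save_snapshots`."""
    with h5py.File(path, "r") as f:
        params = ModelParams(**json.loads(f.attrs["params"]))
        grid = DomainGrid(L=float(f.attrs["L"]), N_g=int(f.attrs["N_g"]),
                          dim=int(f.attrs["dim"]))
        seed = int(f.attrs["seed"])
        snaps = []
        for name in sorted(k for k in f.keys() if k.startswith("snap")):
            g = f[name]
            snaps.append(FieldState(
                t=float(g.attrs["t"]), c=g["c"][...], p_x=g["p_x"][...],
                p_y=g["p_y"][...] if "p_y" in g else None,
                n_a=g["n_a"][...], n_i=g["n_i"][...]))
        return SimResult(snapshots=snaps, params=params, grid=grid,
                         seed=None if seed < 0 else seed,
                         dt_history=f["dt_history"][...],
                         n_accepted=int(f.attrs["n_accepted"]),
                         n_rejected=int(f.attrs["n_rejected"]))


def save_cell_fields(path, state, grid: DomainGrid) -> None:
    """Write one phase-field cell state (c, p, n_a, n_i, psi) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["t"] = state.t
        f.attrs["L"] = grid.L
        f.attrs["N_g"] = grid.N_g
        for name in ("c", "p_x", "p_y", "n_a", "n_i", "psi"):
            f.create_dataset(name, data=getattr(state, name))


def trajectory_to_csv(path, times, centers, areas=None) -> None:
    """Write a cell-center track as CSV columns (t, x, y[, area])."""
    data = {"t": times, "x": centers[:, 0], "y": centers[:, 1]}
    if areas is not None:
        data["area"] = areas
    pd.DataFrame(data).to_csv(path, index=False)


def trajectory_from_csv(path):
    """Read (times, positions) from a (t, x, y) CSV."""
    df = pd.read_csv(path)
    for col in ("t", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"trajectory CSV is missing column {col!r}")
    return df["t"].to_numpy(), df[["x", "y"]].to_numpy()


def dispersion_to_csv(path, curve) -> None:
    """Write a DispersionCurve as CSV (q, re_s_max, im_s_max)."""
    pd.DataFrame({"q": curve.q, "re_s_max": curve.re_s_max,
                  "im_s_max": curve.im_s_max}).to_csv(path, index=False)


def profile_to_csv(path, profile) -> None:
    """Write a WaveProfile as CSV (x, n_a, c, N, n_i)."""
    pd.DataFrame({"x": profile.x, "n_a": profile.n_a, "c": profile.c,
                  "N": profile.N, "n_i": profile.n_i}).to_csv(
        path, index=False)
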