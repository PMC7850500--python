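"""Phase-field cell: actin-nucleator dynamics confined to a deformable cell.

The phase field Psi (~1 inside the cell, ~0 outside; the membrane is the
0.5 level set) obeys

    dPsi/dt = D_psi lap Psi + kappa Psi (1 - Psi)(Psi - delta)
              - beta p . grad Psi,
    delta   = 1/2 + epsilon (integral Psi dA - A_0),

so the double-well term sharpens the interface, delta softly constrains
the cell area to A_0, and the beta term lets the actin polarization push
the membrane.  The actin/nucleator reactions are gated by Psi, and the
nucleators are transported by the mass-conserving current

    dn/dt = D (Psi lap n - n lap Psi)
          = div(D Psi grad n) - div(D n grad Psi),

whose stationary state n ~ Psi confines them to the cell interior without
leaking.  Actin degradation -k_d c acts everywhere so stray actin outside
the cell decays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (BlowUpError, _adaptive_loop, DEFAULT_TOL,
                       DEFAULT_NOISE_FRACTION)
from .grids import DomainGrid, SpectralOps
from .homogeneous import find_fixpoint
from .params import ModelParams, PhaseFieldParams

#: abort threshold for phase-field overshoot (spectral ringing guard)
PSI_GUARD = 1.5
#: default snapshot/trajectory cadence in nondim time
TRAJECTORY_CADENCE = 0.05


@dataclass
class CellState:
    """Fields plus the phase field at one time point (2-D only)."""

    t: float
    c: np.ndarray
    p_x: np.ndarray
    p_y: np.ndarray
    n_a: np.ndarray
    n_i: np.ndarray
    psi: np.ndarray

    def copy(self) -> "CellState":
        return CellState(self.t, self.c.copy(), self.p_x.copy(),
                         self.p_y.copy(), self.n_a.copy(), self.n_i.copy(),
                         self.psi.copy())

    def nucleator_mass(self, grid: DomainGrid) -> float:
        return grid.integrate(self.n_a + self.n_i)

    def area(self, grid: DomainGrid) -> float:
        return grid.integrate(self.psi)


@dataclass
class CellTrajectory:
    """Cell-center track: times, unwrapped 2-D positions, areas."""

    times: np.ndarray
    centers: np.ndarray        # shape (n, 2), unwrapped (continuous)
    areas: np.ndarray

    def displacements(self) -> np.ndarray:
        return self.centers - self.centers[0]


def delta_of_area(psi: np.ndarray, pf: PhaseFieldParams,
                  grid: DomainGrid) -> float:
    """Area-constraint offset delta = 1/2 + epsilon (area - A_0)."""
    return 0.5 + pf.epsilon * (grid.integrate(psi) - pf.A_0)


def conserving_diffusion(n: np.ndarray, psi: np.ndarray, D: float,
                         ops: SpectralOps) -> np.ndarray:
    """Mass-conserving confined transport term D (Psi lap n - n lap Psi).

    Integrates to zero over the periodic box for any n, Psi (the two terms
    cancel in quadrature), and vanishes identically when n is proportional
    to Psi.
    """
    return D * (psi * ops.laplacian(n) - n * ops.laplacian(psi))


def conserving_diffusion_fd(n: np.ndarray, psi: np.ndarray, D: float,
                            h: float) -> np.ndarray:
    """Reference 1-D finite-difference stencil of the confined current:

        D (n_{j+1} Psi_j + n_{j-1} Psi_j - n_j Psi_{j+1} - n_j Psi_{j-1})/h^2

    Equivalent to Psi lap n - n lap Psi with the 3-point Laplacian; hopping
    into site j is weighted by Psi_j, so particles can only move to sites
    inside the cell.
    """
    np_ = np.roll(n, -1)
    nm = np.roll(n, 1)
    pp = np.roll(psi, -1)
    pm = np.roll(psi, 1)
    return D * (np_ * psi + nm * psi - n * pp - n * pm) / h ** 2


def tanh_disk(grid: DomainGrid, center, radius: float,
              width: float) -> np.ndarray:
    """Smoothed-step disk: psi = (1 - tanh((r - radius)/width))/2, with
    periodic minimal-image distance."""
    x, y = grid.coords()
    dx = x - center[0]
    dy = y - center[1]
    L = grid.L
    dx -= L * np.round(dx / L)
    dy -= L * np.round(dy / L)
    r = np.hypot(dx, dy)
    return 0.5 * (1.0 - np.tanh((r - radius) / width))


def init_cell(grid: DomainGrid, params: ModelParams, pf: PhaseFieldParams,
              center=None, interface_width: float | None = None,
              seed: int | None = None,
              noise_amp: float | None = None) -> CellState:
    """Disk-shaped cell of area A_0 with nucleators distributed ~ Psi.

    Total nucleator mass is A_0 * n_tot (intracellular densities then match
    the periodic-box analysis).  The active/inactive split follows the
    homogeneous fixpoint; seeded uniform noise on n_a (compensated on n_i)
    perturbs the interior.  c = p = 0 initially.
    """
    if grid.dim != 2:
        raise ValueError("phase-field cells require a 2-D grid")
    if pf.A_0 >= grid.L ** 2:
        raise ValueError("target area A_0 does not fit in the box")
    if center is None:
        center = (grid.L / 2.0, grid.L / 2.0)
    if interface_width is None:
        interface_width = 3.0 * grid.spacing
    if noise_amp is None:
        noise_amp = DEFAULT_NOISE_FRACTION * params.n_tot
    radius = np.sqrt(pf.A_0 / np.pi)
    if radius + 3 * interface_width > grid.L / 2.0:
        raise ValueError("cell disk does not fit in the box")
    # the smoothed step inflates the area; adjust the radius so the
    # integral hits A_0 (bracketed 1-D solve)
    from scipy.optimize import brentq
    radius = brentq(
        lambda r: grid.integrate(tanh_disk(grid, center, r,
                                           interface_width)) - pf.A_0,
        0.2 * radius, min(1.5 * radius, grid.L / 2 - 3 * interface_width),
        xtol=1e-10)
    psi = tanh_disk(grid, center, radius, interface_width)
    # normalize the total nucleator mass to A_0 * n_tot exactly
    mass_psi = grid.integrate(psi)
    dens = params.n_tot * pf.A_0 / mass_psi
    fix = find_fixpoint(params)
    share_a = fix.n_a0 / params.n_tot
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-noise_amp, noise_amp, size=grid.shape) * psi
    n_a = share_a * dens * psi + delta
    n_i = (1.0 - share_a) * dens * psi - delta
    under_a = np.minimum(n_a, 0.0)
    n_a -= under_a
    n_i += under_a
    under_i = np.minimum(n_i, 0.0)
    n_i -= under_i
    n_a += under_i
    zeros = np.zeros(grid.shape)
    return CellState(t=0.0, c=zeros.copy(), p_x=zeros.copy(),
                     p_y=zeros.copy(), n_a=n_a, n_i=n_i, psi=psi)


def rhs_cell(state: CellState, params: ModelParams, pf: PhaseFieldParams,
             grid: DomainGrid, ops: SpectralOps | None = None) -> dict:
    """Full time derivatives of the confined system (reference path)."""
    if ops is None:
        ops = SpectralOps(grid)
    p = params
    psi = state.psi
    act = (p.omega0 + p.omega * state.n_a ** 2) * state.n_i
    inact = p.omega_d * state.c * state.n_a
    reaction = psi * (act - inact)
    div_p = ops.divergence(state.p_x, state.p_y)
    dc = psi * (p.alpha * state.n_a - p.v_a * div_p) - p.k_d * state.c
    dcx = ops.dx(state.c)
    dcy = ops.dy(state.c)
    dpx = -p.v_a * psi * dcx - p.k_d * state.p_x
    dpy = -p.v_a * psi * dcy - p.k_d * state.p_y
    dna = conserving_diffusion(state.n_a, psi, p.D_a, ops) + reaction
    dni = conserving_diffusion(state.n_i, psi, p.D_i, ops) - reaction
    delta = delta_of_area(psi, pf, grid)
    gx = ops.dx(psi)
    gy = ops.dy(psi)
    dpsi = pf.D_psi * ops.laplacian(psi) \
        + pf.kappa * psi * (1.0 - psi) * (psi - delta) \
        - pf.beta * (state.p_x * gx + state.p_y * gy)
    for name, f in (("c", dc), ("n_a", dna), ("psi", dpsi)):
        if not np.all(np.isfinite(f)):
            raise BlowUpError(f"non-finite d{name}/dt at t={state.t}")
    return {"c": dc, "p_x": dpx, "p_y": dpy, "n_a": dna, "n_i": dni,
            "psi": dpsi}


class _CellStepper:
    """Integrating-factor midpoint stepper for the phase-field system.

    The integrating factor carries exp(-k_d dt) on c, p and full-strength
    diffusion propagators on n_a, n_i, psi; the explicit remainder then
    contains anti-diffusive corrections D((Psi-1) lap n - n lap Psi) whose
    growth is dominated by the propagator's decay (e^-x (1+x) <= 1), so the
    split is stable at reaction-limited step sizes.
    """

    def __init__(self, params: ModelParams, pf: PhaseFieldParams,
                 grid: DomainGrid):
        self.p = params
        self.pf = pf
        self.grid = grid
        self.ops = SpectralOps(grid)
        self._exp_cache: dict = {}

    def nonstiff_rhs(self, y: dict) -> dict:
        p, pf, ops = self.p, self.pf, self.ops
        psi = y["psi"]
        if np.max(np.abs(psi)) > PSI_GUARD:
            raise BlowUpError("phase field overshoot beyond guard (1.5)")
        act = (p.omega0 + p.omega * y["n_a"] ** 2) * y["n_i"]
        inact = p.omega_d * y["c"] * y["n_a"]
        prod = psi * (act - inact)
        F = ops.fwd(np.stack([y["c"], y["p_x"], y["p_y"], y["n_a"],
                              y["n_i"], psi, prod]))
        spec = np.stack([
            ops.ikx * F[0],                    # dx c
            ops.iky * F[0],                    # dy c
            ops.ikx * F[1] + ops.iky * F[2],   # div p
            -ops.q2 * F[3],                    # lap n_a
            -ops.q2 * F[4],                    # lap n_i
            -ops.q2 * F[5],                    # lap psi
            ops.ikx * F[5],                    # dx psi
            ops.iky * F[5],                    # dy psi
            F[6] * ops.dealias_mask,           # dealiased reaction
        ])
        (dcx, dcy, div_p, lap_na, lap_ni, lap_psi, gx, gy,
         reaction) = ops.inv(spec)
        delta = delta_of_area(psi, pf, self.grid)
        return {
            "c": psi * (p.alpha * y["n_a"] - p.v_a * div_p),
            "p_x": -p.v_a * psi * dcx,
            "p_y": -p.v_a * psi * dcy,
            "n_a": p.D_a * ((psi - 1.0) * lap_na
                            - y["n_a"] * lap_psi) + reaction,
            "n_i": p.D_i * ((psi - 1.0) * lap_ni
                            - y["n_i"] * lap_psi) - reaction,
            "psi": pf.kappa * psi * (1.0 - psi) * (psi - delta)
            - pf.beta * (y["p_x"] * gx + y["p_y"] * gy),
        }

    def _exps(self, dt: float):
        hit = self._exp_cache.get(dt)
        if hit is None:
            p, pf, ops = self.p, self.pf, self.ops
            Ds = np.array([p.D_a, p.D_i, pf.D_psi])[:, None, None]
            hit = (np.exp(-Ds * ops.q2 * dt), np.exp(-p.k_d * dt))
            if len(self._exp_cache) > 12:
                self._exp_cache.clear()
            self._exp_cache[dt] = hit
        return hit

    def apply_propagator(self, y: dict, dt: float) -> dict:
        ops = self.ops
        diff, decay = self._exps(dt)
        na, ni, psi = ops.inv(
            ops.fwd(np.stack([y["n_a"], y["n_i"], y["psi"]])) * diff)
        return {
            "c": y["c"] * decay,
            "p_x": y["p_x"] * decay,
            "p_y": y["p_y"] * decay,
            "n_a": na,
            "n_i": ni,
            "psi": psi,
        }

    def midpoint_step(self, y: dict, dt: float,
                      f_y: dict | None = None) -> dict:
        if f_y is None:
            f_y = self.nonstiff_rhs(y)
        half = {k: y[k] + 0.5 * dt * f_y[k] for k in y}
        u = self.apply_propagator(half, 0.5 * dt)
        f_u = self.nonstiff_rhs(u)
        prop = self.apply_propagator(y, dt)
        incr = self.apply_propagator({k: dt * f_u[k] for k in y}, 0.5 * dt)
        return {k: prop[k] + incr[k] for k in y}


def cell_center(psi: np.ndarray, grid: DomainGrid) -> np.ndarray:
    """Area-normalized centroid of the phase field, periodic-aware.

    Each coordinate is mapped to an angle on the circle of circumference L,
    averaged with weight psi, and mapped back; robust when the cell spans
    the box edge.  Raises when psi carries no weight.
    """
    w = psi.sum()
    if w <= 1e-12:
        raise ValueError("phase field is (numerically) zero everywhere")
    L = grid.L
    x = np.arange(grid.N_g) * grid.spacing
    out = np.empty(2)
    for axis in (0, 1):
        wx = psi.sum(axis=1 - axis)
        theta = 2.0 * np.pi * x / L
        C = np.sum(wx * np.cos(theta))
        S = np.sum(wx * np.sin(theta))
        out[axis] = (np.arctan2(S, C) / (2.0 * np.pi) * L) % L
    return out


def unwrap_track(centers_raw: np.ndarray, L: float) -> np.ndarray:
    """Make a periodic center track continuous by minimal-image unwrapping
    of consecutive frame-to-frame displacements."""
    centers = np.asarray(centers_raw, dtype=float)
    steps = np.diff(centers, axis=0)
    steps -= L * np.round(steps / L)
    out = np.empty_like(centers)
    out[0] = centers[0]
    out[1:] = centers[0] + np.cumsum(steps, axis=0)
    return out


def integrate_cell(state: CellState, params: ModelParams,
                   pf: PhaseFieldParams, grid: DomainGrid, t_end: float,
                   tol: float = DEFAULT_TOL,
                   snapshot_dt: float | None = TRAJECTORY_CADENCE,
                   seed: int | None = None,
                   control_interval: int = 1,
                   track_dt: float | None = None):
    """Integrate the coupled cell system; returns (snapshots, stats dict).

    ``track_dt`` records the cell-center track (t, r_c, area) at that
    cadence without storing full snapshots; the track appears in the stats
    dict as ``track`` = (times, centers_raw, areas).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    stepper = _CellStepper(params, pf, grid)
    y = {"c": state.c.copy(), "p_x": state.p_x.copy(),
         "p_y": state.p_y.copy(), "n_a": state.n_a.copy(),
         "n_i": state.n_i.copy(), "psi": state.psi.copy()}
    nscale = max(params.n_tot, 1.0)
    scales = {"c": params.alpha * params.n_tot / max(params.k_d, 1.0),
              "p_x": nscale, "p_y": nscale, "n_a": nscale, "n_i": nscale,
              "psi": 1.0}

    def make_state(yv, t):
        return CellState(t, yv["c"].copy(), yv["p_x"].copy(),
                         yv["p_y"].copy(), yv["n_a"].copy(),
                         yv["n_i"].copy(), yv["psi"].copy())

    track: list = []
    observer = None
    if track_dt is not None:
        next_obs = [state.t]

        def observer(t, yv):
            if t >= next_obs[0] - 1e-12:
                track.append((t, cell_center(yv["psi"], grid),
                              grid.integrate(yv["psi"])))
                next_obs[0] = t + track_dt

    snaps, dts, n_acc, n_rej = _adaptive_loop(
        stepper, y, state.t, state.t + t_end, tol, scales, snapshot_dt,
        make_state, control_interval=control_interval, observer=observer)
    stats = {"dt_history": dts, "n_accepted": n_acc, "n_rejected": n_rej,
             "seed": seed}
    if track_dt is not None:
        stats["track"] = (np.array([r[0] for r in track]),
                          np.array([r[1] for r in track]),
                          np.array([r[2] for r in track]))
    return snaps, stats


def track_from_snapshots(snaps, grid: DomainGrid) -> CellTrajectory:
    """Cell-center trajectory (periodic-unwrapped) from snapshots."""
    times = np.array([s.t for s in snaps])
    raw = np.array([cell_center(s.psi, grid) for s in snaps])
    centers = unwrap_track(raw, grid.L)
    areas = np.array([s.area(grid) for s in snaps])
    return CellTrajectory(times=times, centers=centers, areas=areas)


def run_migration(params: ModelParams, pf: PhaseFieldParams,
                  grid: DomainGrid, t_end: float, seed: int | None = None,
                  tol: float = DEFAULT_TOL,
                  snapshot_dt: float = 10 * TRAJECTORY_CADENCE,
                  track_dt: float = TRAJECTORY_CADENCE,
                  noise_amp: float | None = None,
                  control_interval: int = 1):
    """Simulate a migrating cell from the standard disk initial condition.

    The center track is recorded densely (cadence ``track_dt``,
    interpolated to uniform sampling); full field snapshots are kept at
    the sparser ``snapshot_dt``.  Returns (CellTrajectory, snapshots).
    """
    state = init_cell(grid, params, pf, seed=seed, noise_amp=noise_amp)
    snaps, stats = integrate_cell(state, params, pf, grid, t_end, tol=tol,
                                  snapshot_dt=snapshot_dt, seed=seed,
                                  control_interval=control_interval,
                                  track_dt=track_dt)
    times, raw, areas = stats["track"]
    centers = unwrap_track(raw, grid.L)
    # resample to uniform cadence (accepted-step times are irregular)
    t_uni = np.arange(times[0], times[-1] + 1e-12, track_dt)
    cx = np.interp(t_uni, times, centers[:, 0])
    cy = np.interp(t_uni, times, centers[:, 1])
    a_uni = np.interp(t_uni, times, areas)
    traj = CellTrajectory(times=t_uni,
                          centers=np.column_stack([cx, cy]),
                          areas=a_uni)
    return traj, snaps
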