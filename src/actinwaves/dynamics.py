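"""Pseudo-spectral solver for the actin-nucleator PDEs on periodic domains.

The five fields are the actin density c, the polarization p (p_x, p_y; a
scalar in 1-D), and the active/inactive nucleator densities n_a, n_i:

    dc/dt   = -v_a div p - k_d c + alpha n_a
    dp/dt   = -v_a grad c - k_d p
    dn_a/dt = D_a lap n_a + (omega0 + omega n_a^2) n_i - omega_d c n_a
    dn_i/dt = D_i lap n_i - (omega0 + omega n_a^2) n_i + omega_d c n_a

Spatial derivatives are Fourier differentiation; nonlinear products are
dealiased by the 2/3 rule.  Time stepping is the explicit midpoint rule
with step-doubling error control, with the stiff diagonal linear terms
(diffusion, -k_d decay) removed by an exact integrating factor so that the
step size is set by the reaction dynamics, not by the grid.

Total nucleator mass is conserved to machine precision: the activation /
inactivation exchange terms cancel pointwise between the two nucleator
equations, and diffusion leaves the spatial mean untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .grids import DomainGrid, SpectralOps
from .homogeneous import find_fixpoint
from .params import ModelParams

#: default per-step error tolerance (max-norm, relative to field scale)
DEFAULT_TOL = 1e-6
#: default initial-noise amplitude as a fraction of n_tot
DEFAULT_NOISE_FRACTION = 0.01


@dataclass
class FieldState:
    """Fields on a periodic grid at one time point.

    p_y is None on 1-D grids.
    """

    t: float
    c: np.ndarray
    p_x: np.ndarray
    p_y: np.ndarray | None
    n_a: np.ndarray
    n_i: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.c.copy(), self.p_x.copy(),
                          None if self.p_y is None else self.p_y.copy(),
                          self.n_a.copy(), self.n_i.copy())

    def nucleator_mass(self, grid: DomainGrid) -> float:
        return grid.integrate(self.n_a + self.n_i)


@dataclass
class SimResult:
    """Time-ordered snapshots plus run metadata."""

    snapshots: list
    params: ModelParams
    grid: DomainGrid
    seed: int | None
    dt_history: np.ndarray
    n_accepted: int
    n_rejected: int

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    @property
    def final(self) -> FieldState:
        return self.snapshots[-1]


class BlowUpError(RuntimeError):
    """Raised when the solution develops NaN/Inf or dt underflows."""


def init_fields(grid: DomainGrid, params: ModelParams,
                noise_amp: float | None = None,
                seed: int | None = None) -> FieldState:
    """Homogeneous fixpoint plus seeded uniform noise on n_a.

    The perturbation is subtracted from n_i pointwise, so n_a + n_i equals
    n_tot everywhere and total nucleator mass is conserved exactly.  If
    the noise would push n_i negative it is clipped with the clipped amount
    returned to n_a (keeping the sum exact).
    """
    if noise_amp is None:
        noise_amp = DEFAULT_NOISE_FRACTION * params.n_tot
    if noise_amp < 0:
        raise ValueError("noise_amp must be >= 0")
    fix = find_fixpoint(params)
    shape = grid.shape
    rng = np.random.default_rng(seed)
    delta = rng.uniform(-noise_amp, noise_amp, size=shape)
    n_a = np.full(shape, fix.n_a0) + delta
    n_i = np.full(shape, fix.n_i0) - delta
    # keep both densities nonnegative without touching the exact sum
    under_a = np.minimum(n_a, 0.0)
    n_a -= under_a
    n_i += under_a
    under_i = np.minimum(n_i, 0.0)
    n_i -= under_i
    n_a += under_i
    zeros = np.zeros(shape)
    return FieldState(t=0.0, c=np.full(shape, fix.c0), p_x=zeros.copy(),
                      p_y=zeros.copy() if grid.dim == 2 else None,
                      n_a=n_a, n_i=n_i)


def _reaction_terms(state: FieldState, params: ModelParams,
                    ops: SpectralOps, dealias: bool = True):
    """Dealiased activation and inactivation products."""
    p = params
    act = (p.omega0 + p.omega * state.n_a ** 2) * state.n_i
    inact = p.omega_d * state.c * state.n_a
    if dealias:
        act = ops.dealias(act)
        inact = ops.dealias(inact)
    return act, inact


def rhs_fields(state: FieldState, params: ModelParams,
               grid: DomainGrid, ops: SpectralOps | None = None,
               dealias: bool = False) -> dict:
    """Full time derivatives of all fields (reference/diagnostic path).

    The production integrator splits off the diffusion and decay terms; this
    function assembles the complete right-hand side, checks for blow-up and
    is the target of the finite-difference oracle tests.
    """
    if ops is None:
        ops = SpectralOps(grid)
    p = params
    act, inact = _reaction_terms(state, params, ops, dealias=dealias)
    if grid.dim == 2:
        div_p = ops.divergence(state.p_x, state.p_y)
        dc = -p.v_a * div_p - p.k_d * state.c + p.alpha * state.n_a
        dpx = -p.v_a * ops.dx(state.c) - p.k_d * state.p_x
        dpy = -p.v_a * ops.dy(state.c) - p.k_d * state.p_y
    else:
        dc = -p.v_a * ops.dx(state.p_x) - p.k_d * state.c \
            + p.alpha * state.n_a
        dpx = -p.v_a * ops.dx(state.c) - p.k_d * state.p_x
        dpy = None
    dna = p.D_a * ops.laplacian(state.n_a) + act - inact
    dni = p.D_i * ops.laplacian(state.n_i) - act + inact
    for name, f in (("c", dc), ("n_a", dna), ("n_i", dni)):
        if not np.all(np.isfinite(f)):
            raise BlowUpError(f"non-finite d{name}/dt at t={state.t}")
    return {"c": dc, "p_x": dpx, "p_y": dpy, "n_a": dna, "n_i": dni}


class _PeriodicStepper:
    """Integrating-factor explicit-midpoint stepper for the periodic box.

    State vector y = (c, p_x[, p_y], n_a, n_i).  The integrating factor
    handles exp(-k_d dt) on c and p and exp(-D q^2 dt) on the nucleators;
    the explicit part holds the advective couplings and the reaction terms.
    """

    def __init__(self, params: ModelParams, grid: DomainGrid):
        self.p = params
        self.grid = grid
        self.ops = SpectralOps(grid)
        self._exp_cache: dict = {}

    def nonstiff_rhs(self, y: dict) -> dict:
        p, ops = self.p, self.ops
        act = (p.omega0 + p.omega * y["n_a"] ** 2) * y["n_i"]
        inact = p.omega_d * y["c"] * y["n_a"]
        if self.grid.dim == 2:
            F = ops.fwd(np.stack([y["c"], y["p_x"], y["p_y"],
                                  act, inact]))
            spec = np.stack([
                ops.ikx * F[0],                      # dx c
                ops.iky * F[0],                      # dy c
                ops.ikx * F[1] + ops.iky * F[2],     # div p
                F[3] * ops.dealias_mask,
                F[4] * ops.dealias_mask,
            ])
            dcx, dcy, div_p, act_f, inact_f = ops.inv(spec)
            react = act_f - inact_f
            return {
                "c": -p.v_a * div_p + p.alpha * y["n_a"],
                "p_x": -p.v_a * dcx,
                "p_y": -p.v_a * dcy,
                "n_a": react,
                "n_i": -react,
            }
        F = ops.fwd(np.stack([y["c"], y["p_x"], act, inact]))
        spec = np.stack([
            ops.ikx * F[0],
            ops.ikx * F[1],
            F[2] * ops.dealias_mask,
            F[3] * ops.dealias_mask,
        ])
        dcx, dpx, act_f, inact_f = ops.inv(spec)
        react = act_f - inact_f
        return {
            "c": -p.v_a * dpx + p.alpha * y["n_a"],
            "p_x": -p.v_a * dcx,
            "n_a": react,
            "n_i": -react,
        }

    def _exps(self, dt: float):
        """Cached diffusion propagators for n_a, n_i and the decay scalar."""
        hit = self._exp_cache.get(dt)
        if hit is None:
            p, ops = self.p, self.ops
            hit = (np.exp(-np.array([p.D_a, p.D_i])[:, None, None]
                          * ops.q2 * dt) if self.grid.dim == 2 else
                   np.exp(-np.array([p.D_a, p.D_i])[:, None]
                          * ops.q2 * dt),
                   np.exp(-p.k_d * dt))
            if len(self._exp_cache) > 12:
                self._exp_cache.clear()
            self._exp_cache[dt] = hit
        return hit

    def apply_propagator(self, y: dict, dt: float) -> dict:
        ops = self.ops
        diff, decay = self._exps(dt)
        na, ni = ops.inv(ops.fwd(np.stack([y["n_a"], y["n_i"]])) * diff)
        out = {"c": y["c"] * decay, "p_x": y["p_x"] * decay,
               "n_a": na, "n_i": ni}
        if self.grid.dim == 2:
            out["p_y"] = y["p_y"] * decay
        return out

    def midpoint_step(self, y: dict, dt: float,
                      f_y: dict | None = None) -> dict:
        """One integrating-factor midpoint step of size dt."""
        if f_y is None:
            f_y = self.nonstiff_rhs(y)
        half = {k: y[k] + 0.5 * dt * f_y[k] for k in y}
        u = self.apply_propagator(half, 0.5 * dt)
        f_u = self.nonstiff_rhs(u)
        prop = self.apply_propagator(y, dt)
        incr = self.apply_propagator({k: dt * f_u[k] for k in y}, 0.5 * dt)
        return {k: prop[k] + incr[k] for k in y}


def _state_to_vec(state: FieldState, dim: int) -> dict:
    y = {"c": state.c, "p_x": state.p_x, "n_a": state.n_a, "n_i": state.n_i}
    if dim == 2:
        y["p_y"] = state.p_y
    return y


def _vec_to_state(y: dict, t: float, dim: int) -> FieldState:
    return FieldState(t=t, c=y["c"], p_x=y["p_x"],
                      p_y=y.get("p_y"), n_a=y["n_a"], n_i=y["n_i"])


def _adaptive_loop(stepper, y: dict, t0: float, t_end: float, tol: float,
                   scales: dict, snapshot_dt: float | None,
                   make_state: Callable, dt0: float = 1e-5,
                   dt_min: float = 1e-12, max_ratio: float = 5.0,
                   control_interval: int = 1, observer: Callable = None):
    """Shared step-doubling driver; returns (snapshots, dts, n_acc, n_rej).

    Error estimate: one full step vs two half steps, per-field max norm
    scaled by ``scales``; accepted solution is the two-half-step one.
    With ``control_interval`` = K > 1 the error is re-estimated every K-th
    step and the intermediate steps run plain midpoint at the current dt
    (cadenced control; cheaper, used for long production runs).
    ``observer(t, y)`` is called after every accepted step.
    """
    t, dt = t0, dt0
    snapshots = [make_state(y, t)]
    if observer is not None:
        observer(t, y)
    next_snap = t + snapshot_dt if snapshot_dt else np.inf
    dts, n_acc, n_rej = [], 0, 0

    def accept(t, y):
        nonlocal n_acc, next_snap
        n_acc += 1
        dts.append(dt)
        if observer is not None:
            observer(t, y)
        if t >= next_snap - 1e-12:
            snapshots.append(make_state(y, t))
            next_snap += snapshot_dt

    while t < t_end - 1e-14:
        dt = min(dt, t_end - t)
        f_y = stepper.nonstiff_rhs(y)
        y_big = stepper.midpoint_step(y, dt, f_y)
        y_half = stepper.midpoint_step(y, 0.5 * dt, f_y)
        y_small = stepper.midpoint_step(y_half, 0.5 * dt)
        err = 0.0
        for k in y:
            e = np.max(np.abs(y_big[k] - y_small[k])) / scales[k]
            err = max(err, e)
        if not np.isfinite(err):
            err = np.inf
        if err <= tol:
            t += dt
            y = y_small
            accept(t, y)
            # free-running midpoint steps until the next error check
            for _ in range(control_interval - 1):
                if t >= t_end - 1e-14:
                    break
                dt_free = min(dt, t_end - t)
                y_new = stepper.midpoint_step(y, dt_free)
                if not np.all(np.isfinite(y_new["n_a"])):
                    break  # re-enter controlled stepping
                t += dt_free
                y = y_new
                accept(t, y)
        else:
            n_rej += 1
        factor = 0.9 * (tol / err) ** (1.0 / 3.0) if err > 0 else max_ratio
        dt = dt * min(max(factor, 0.2), max_ratio)
        if dt < dt_min:
            raise BlowUpError(f"step size underflow (dt={dt:.3e}) at t={t}")
    if not snapshots or snapshots[-1].t < t_end - 1e-12:
        snapshots.append(make_state(y, t))
    return snapshots, np.array(dts), n_acc, n_rej


def integrate(state: FieldState, params: ModelParams, grid: DomainGrid,
              t_end: float, tol: float = DEFAULT_TOL,
              snapshot_dt: float | None = None,
              seed: int | None = None,
              control_interval: int = 1) -> SimResult:
    """Integrate the periodic-box system from ``state`` to ``t_end``.

    ``snapshot_dt`` sets the snapshot cadence (None: only initial and final
    states are kept).  ``seed`` is recorded metadata only; the dynamics is
    deterministic.  ``control_interval`` > 1 re-estimates the step error
    only every K-th step (cheaper long runs).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    stepper = _PeriodicStepper(params, grid)
    y = _state_to_vec(state.copy(), grid.dim)
    fix_scale = max(params.n_tot, 1.0)
    scales = {k: max(float(np.max(np.abs(v))), fix_scale)
              for k, v in y.items()}
    scales["c"] = max(scales["c"], params.alpha * params.n_tot
                      / max(params.k_d, 1.0))
    snaps, dts, n_acc, n_rej = _adaptive_loop(
        stepper, y, state.t, state.t + t_end, tol, scales, snapshot_dt,
        lambda yv, t: _vec_to_state({k: v.copy() for k, v in yv.items()},
                                    t, grid.dim),
        control_interval=control_interval)
    return SimResult(snapshots=snaps, params=params, grid=grid, seed=seed,
                     dt_history=dts, n_accepted=n_acc, n_rejected=n_rej)
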