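"""Spatially homogeneous actin-nucleator dynamics and its bifurcations.

With uniform fields the polarization decays and the model reduces to two
ODEs for the actin density c and the active-nucleator density n_a (the
inactive pool is slaved, n_i = n_tot - n_a):

    dc/dt   = -k_d c + alpha n_a
    dn_a/dt = (1 + omega n_a^2)(n_tot - n_a) - omega_d c n_a

This is a FitzHugh-Nagumo-like activator/inhibitor pair: the nucleators are
the (autocatalytic) driver, actin the slow carrier that feeds back
negatively.  The module locates the unique fixpoint, analyzes its linear
stability, classifies the dynamics (stable / oscillatory / excitable), and
provides the reference FitzHugh-Nagumo system for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .params import ModelParams

DynClass = Literal["stable_stationary", "oscillatory", "excitable"]

#: composite-parameter threshold above which the n_a-nullcline has two
#: positive extrema (necessary condition for oscillations)
EXTREMA_THRESHOLD = 27.0


@dataclass(frozen=True)
class HomogeneousState:
    """Point (c, n_a) in the homogeneous phase plane."""

    c: float
    n_a: float


@dataclass(frozen=True)
class CubicExtrema:
    """Real roots of the nullcline-derivative cubic.

    The extrema of the n_a-nullcline c(n_a) solve

        0 = -n_tot - 2 omega n_a^3 + omega n_tot n_a^2.

    One real root is always negative; two additional (positive) real roots
    exist iff omega * n_tot^2 > 27.
    """

    roots: tuple
    has_three: bool
    n_a_minus: float | None = None
    n_a_zero: float | None = None
    n_a_plus: float | None = None


@dataclass(frozen=True)
class FixpointInfo:
    """Unique homogeneous steady state and its linear stability."""

    c0: float
    n_a0: float
    n_i0: float
    eigenvalues: tuple
    dyn_class: DynClass


def rhs_homogeneous(state: HomogeneousState | tuple,
                    params: ModelParams) -> tuple:
    """Time derivatives (dc/dt, dn_a/dt) of the homogeneous system."""
    c, n_a = (state.c, state.n_a) if isinstance(state, HomogeneousState) \
        else state
    p = params
    dc = -p.k_d * c + p.alpha * n_a
    dna = (p.omega0 + p.omega * n_a ** 2) * (p.n_tot - n_a) \
        - p.omega_d * c * n_a
    return dc, dna


def nullcline_c_of_na(n_a, params: ModelParams):
    """The n_a-nullcline c(n_a) = (1 + omega n_a^2)(n_tot - n_a)/(omega_d n_a).

    Diverges to +inf as n_a -> 0+ and to -inf as n_a -> inf.  Requires
    n_a > 0 and omega_d > 0.
    """
    n_a = np.asarray(n_a, dtype=float)
    if np.any(n_a <= 0):
        raise ValueError("nullcline requires n_a > 0")
    if params.omega_d <= 0:
        raise ValueError("nullcline undefined for omega_d = 0")
    p = params
    num = p.n_tot - p.omega * n_a ** 3 + p.omega * p.n_tot * n_a ** 2 - n_a
    return num / (p.omega_d * n_a)


def nullcline_tangent_intercept(n_a, params: ModelParams):
    """y-intercept of the tangent to the n_a-nullcline, up to the positive
    factor 1/(omega_d n_a):  c_y ~ omega n_a^3 + 2 n_tot - n_a.

    Positive for all 0 <= n_a <= n_tot, which is why the two nullclines can
    only intersect once (no bistability in this model).
    """
    n_a = np.asarray(n_a, dtype=float)
    return params.omega * n_a ** 3 + 2.0 * params.n_tot - n_a


def extrema_roots(params: ModelParams, rtol: float = 1e-9) -> CubicExtrema:
    """Real roots of the nullcline-extrema cubic, via the companion matrix.

    Labels the roots as n_a_minus (always negative), n_a_zero and n_a_plus
    (the two positive ones, n_a_zero <= n_a_plus) when three real roots
    exist, i.e. when omega * n_tot^2 > 27.
    """
    w, nt = params.omega, params.n_tot
    if w == 0:
        # cubic degenerates to 0 = -n_tot: no extrema at all
        return CubicExtrema(roots=(), has_three=False)
    coeffs = [-2.0 * w, w * nt, 0.0, -nt]
    all_roots = np.roots(coeffs)
    scale = max(abs(all_roots).max(), 1.0)
    # a numerically split double root (at the threshold) has imaginary part
    # ~ sqrt(machine eps) * scale, so the reality tolerance must sit above it
    real = np.sort(np.real(all_roots[np.abs(all_roots.imag) < 1e-6 * scale]))
    has_three = len(real) == 3 and w * nt ** 2 > EXTREMA_THRESHOLD
    if has_three:
        return CubicExtrema(roots=tuple(real), has_three=True,
                            n_a_minus=real[0], n_a_zero=real[1],
                            n_a_plus=real[2])
    return CubicExtrema(roots=tuple(real), has_three=False,
                        n_a_minus=real[0])


def extrema_roots_trig(params: ModelParams) -> tuple:
    """Closed-form (trigonometric) roots of the extrema cubic, cross-check.

    Uses the standard depressed-cubic solution: with
    phi = arccos(1 - 54/(omega n_tot^2)) the three roots are
    n_tot/6 * (1 + 2 cos((phi - 2 pi k)/3)), k = 0, 1, 2, valid for
    omega n_tot^2 >= 27.  Returns (n_a_plus, n_a_zero, n_a_minus).

    Note: an arcsine-branch variant of these formulas matches this solution
    only if its argument is taken as 54/(omega n_tot^2) - 1; with the
    opposite sign it agrees at omega n_tot^2 = 54 but gives n_tot/2 instead
    of the correct double root n_tot/3 at the boundary 27 (see
    :func:`extrema_roots_arcsine_branch`).
    """
    w, nt = params.omega, params.n_tot
    x = w * nt ** 2
    if x < EXTREMA_THRESHOLD:
        raise ValueError("closed forms require omega * n_tot^2 >= 27")
    phi = np.arccos(np.clip(1.0 - 54.0 / x, -1.0, 1.0))
    roots = [nt / 6.0 * (1.0 + 2.0 * np.cos((phi - 2.0 * np.pi * k) / 3.0))
             for k in range(3)]
    return roots[0], roots[1], roots[2]   # plus, zero, minus


def extrema_roots_arcsine_branch(params: ModelParams,
                                 flip_sign: bool = False) -> tuple:
    """Arcsine-branch closed forms for the extrema roots (cross-check only).

    With theta = arcsin(z), z = 1 - 54/(omega n_tot^2) (or its negative if
    ``flip_sign``), returns

        n_a_plus/minus = n_tot/6 (1 +/- 2 sin[(pi - theta)/3])
        n_a_zero       = n_tot/6 (1 + 2 sin[theta/3])

    The ``flip_sign=True`` branch coincides with the correct trigonometric
    solution everywhere; the ``flip_sign=False`` branch only at
    omega n_tot^2 = 54.
    """
    w, nt = params.omega, params.n_tot
    z = 1.0 - 54.0 / (w * nt ** 2)
    if flip_sign:
        z = -z
    theta = np.arcsin(np.clip(z, -1.0, 1.0))
    s = np.sin((np.pi - theta) / 3.0)
    na_plus = nt / 6.0 * (1.0 + 2.0 * s)
    na_minus = nt / 6.0 * (1.0 - 2.0 * s)
    na_zero = nt / 6.0 * (1.0 + 2.0 * np.sin(theta / 3.0))
    return na_plus, na_zero, na_minus


def _fixpoint_residual(n_a: float, params: ModelParams) -> float:
    """g(n_a) = (1 + omega n_a^2)(n_tot - n_a) - omega_d (alpha/k_d) n_a^2."""
    p = params
    return (p.omega0 + p.omega * n_a ** 2) * (p.n_tot - n_a) \
        - p.omega_d * (p.alpha / p.k_d) * n_a ** 2


def jacobian_homogeneous(n_a0: float, c0: float,
                         params: ModelParams) -> np.ndarray:
    """2x2 Jacobian of the homogeneous system at (c0, n_a0), rows (c, n_a)."""
    p = params
    a = -p.omega0 - 3.0 * p.omega * n_a0 ** 2 \
        + 2.0 * p.omega * p.n_tot * n_a0 - p.omega_d * c0
    return np.array([[-p.k_d, p.alpha],
                     [-p.omega_d * n_a0, a]])


def oscillation_frequency_estimate(params: ModelParams,
                                   n_a0: float) -> float:
    """Estimate of the oscillation frequency near onset,
    omega_F = sqrt(alpha omega_d n_a0)."""
    return float(np.sqrt(params.alpha * params.omega_d * n_a0))


def find_fixpoint(params: ModelParams, xtol: float = 1e-12) -> FixpointInfo:
    """Locate the unique homogeneous steady state in [0, n_tot].

    Solves (1 + omega n_a^2)(n_tot - n_a) = omega_d (alpha/k_d) n_a^2 by
    bracketed root finding; the bracket [0, n_tot] is guaranteed because the
    residual is +n_tot omega0 at 0 and <= 0 at n_tot.
    """
    p = params
    if p.k_d <= 0:
        raise ValueError("fixpoint requires k_d > 0")
    g0 = _fixpoint_residual(0.0, p)
    gN = _fixpoint_residual(p.n_tot, p)
    if g0 == 0.0:
        n_a0 = 0.0
    elif gN == 0.0:
        n_a0 = p.n_tot
    elif g0 * gN > 0:
        raise RuntimeError("fixpoint root not bracketed in [0, n_tot]; "
                           "this indicates a solver bug")
    else:
        n_a0 = brentq(_fixpoint_residual, 0.0, p.n_tot, args=(p,),
                      xtol=xtol, rtol=8.9e-16)
    c0 = p.alpha * n_a0 / p.k_d
    eig = np.linalg.eigvals(jacobian_homogeneous(n_a0, c0, p))
    eig = tuple(sorted(eig, key=lambda s: (-s.real, -abs(s.imag))))
    dyn = classify_homogeneous(p, _fix=(c0, n_a0, eig))
    return FixpointInfo(c0=c0, n_a0=n_a0, n_i0=p.n_tot - n_a0,
                        eigenvalues=eig, dyn_class=dyn)


# ---------------------------------------------------------------------------
# classification

#: finite kicks applied to n_a when probing excitability, as fractions of
#: n_tot; escalating sizes because the excitation threshold moves with the
#: inactivation rate omega_d
EXCITABILITY_KICKS = (0.2, 0.3, 0.4, 0.5)
#: ratio of nonlinear to linear-response actin excursion above which the
#: fixpoint counts as excitable
EXCITABILITY_GAIN = 5.0


def _peak_actin_excursion(params: ModelParams, c0: float, n_a0: float,
                          kick: float, linear: bool) -> float:
    """Peak |c - c0| after kicking n_a by ``kick``, for the full or the
    linearized dynamics."""
    if linear:
        J = jacobian_homogeneous(n_a0, c0, params)

        def rhs(t, y):
            return J @ y

        y0 = [0.0, kick]
    else:
        def rhs(t, y):
            return rhs_homogeneous((y[0], y[1]), params)

        y0 = [c0, min(n_a0 + kick, params.n_tot)]
    # excursions play out on tens of actin turnover times 1/k_d
    t_end = 500.0 / params.k_d
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="RK45",
                    rtol=1e-8, atol=1e-10, dense_output=True)
    t = np.linspace(0.0, t_end, 2000)
    c_t = sol.sol(t)[0]
    if linear:
        return float(np.max(np.abs(c_t)))
    return float(np.max(np.abs(c_t - c0)))


def classify_homogeneous(params: ModelParams, _fix=None) -> DynClass:
    """Classify the homogeneous dynamics.

    oscillatory       -- fixpoint linearly unstable (limit cycle);
    excitable         -- fixpoint stable, the nullcline has two positive
                         extrema with the fixpoint outside the unstable
                         branch, and a finite kick of the nucleator density
                         (0.2 n_tot) triggers an actin excursion more than
                         5x the linear-response prediction;
    stable_stationary -- otherwise.
    """
    p = params
    if _fix is None:
        n_a0 = brentq(_fixpoint_residual, 0.0, p.n_tot, args=(p,),
                      xtol=1e-12, rtol=8.9e-16) \
            if _fixpoint_residual(0.0, p) * _fixpoint_residual(p.n_tot, p) < 0 \
            else (0.0 if _fixpoint_residual(0.0, p) == 0 else p.n_tot)
        c0 = p.alpha * n_a0 / p.k_d
        eig = np.linalg.eigvals(jacobian_homogeneous(n_a0, c0, p))
    else:
        c0, n_a0, eig = _fix
    if max(np.real(eig)) > 0.0:
        return "oscillatory"
    ext = extrema_roots(p)
    if not ext.has_three:
        return "stable_stationary"
    # the kick must push n_a over the nearest extremum of the S-shaped
    # nullcline: down if the fixpoint sits on the high branch, up otherwise
    direction = -1.0 if n_a0 >= ext.n_a_plus else 1.0
    for frac in EXCITABILITY_KICKS:
        kick = direction * frac * p.n_tot
        if n_a0 + kick < 0.0:
            kick = -n_a0
        peak_nl = _peak_actin_excursion(p, c0, n_a0, kick, linear=False)
        peak_lin = _peak_actin_excursion(p, c0, n_a0, kick, linear=True)
        if peak_lin > 0 and peak_nl > EXCITABILITY_GAIN * peak_lin:
            return "excitable"
    return "stable_stationary"


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo reference system

FHNClass = Literal["bistable", "limit_cycle", "excitable"]


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh-Nagumo parameters: (1/eps) dw/dt = v - a w,
    dv/dt = -w + I + f(v), f(v) = v - v^3/3."""

    a: float
    I: float
    eps: float = 0.05

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps must be > 0")


def fhn_rhs(state, p: FHNParams):
    """Time derivatives (dv/dt, dw/dt) of the FHN system."""
    v, w = state
    dv = -w + p.I + v - v ** 3 / 3.0
    dw = p.eps * (v - p.a * w)
    return dv, dw


def classify_fhn(p: FHNParams) -> FHNClass:
    """Classify the FHN phase plane by its nullcline intersections.

    Intersections solve -v^3/3 + (1 - 1/a) v + I = 0.  Three real
    solutions -> bistable.  One -> limit cycle if it lies between the
    extrema of the cubic nullcline (|v*| < 1, where the branch is
    destabilizing), else excitable.
    """
    if p.a <= 0:
        raise ValueError("classification requires a > 0")
    coeffs = [-1.0 / 3.0, 0.0, 1.0 - 1.0 / p.a, p.I]
    roots = np.roots(coeffs)
    scale = max(1.0, abs(roots).max())
    real = np.sort(roots[np.abs(roots.imag) < 1e-9 * scale].real)
    if len(real) == 3 and real[2] - real[0] > 1e-9 * scale:
        return "bistable"
    v_star = float(real[0]) if len(real) == 1 else \
        float(np.real(roots[np.argmin(np.abs(roots.imag))]))
    return "limit_cycle" if abs(v_star) < 1.0 else "excitable"


# ---------------------------------------------------------------------------
# shared 0-D integrator

def integrate_ode(rhs: Callable, initial: Sequence[float],
                  t_span: tuple, tol: float = 1e-8,
                  n_eval: int = 2000):
    """Adaptive integration of a small ODE system (scipy RK45).

    Returns (t, y) sampled on ``n_eval`` uniform points.  Raises
    RuntimeError with the last state if the solver fails (divergence or
    step-size underflow).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")

    def f(t, y):
        return rhs(y)

    sol = solve_ivp(f, t_span, list(initial), method="RK45",
                    rtol=tol, atol=tol * 1e-2, dense_output=True)
    if not sol.success:
        raise RuntimeError(
            f"integration failed: {sol.message}; last state {sol.y[:, -1]}")
    t = np.linspace(t_span[0], t_span[1], n_eval)
    return t, sol.sol(t)


def limit_cycle_period(t: np.ndarray, signal: np.ndarray,
                       discard_fraction: float = 0.5) -> float:
    """Period of a limit cycle from successive-maxima timing.

    Discards the leading transient, finds local maxima of the signal and
    returns the mean spacing.  Raises if fewer than two maxima remain.
    """
    i0 = int(len(t) * discard_fraction)
    s = signal[i0:]
    peaks, _ = find_peaks(s, prominence=0.01 * max(np.ptp(s), 1e-300))
    if len(peaks) < 2:
        raise ValueError("no sustained oscillation detected")
    return float(np.mean(np.diff(t[i0:][peaks])))
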