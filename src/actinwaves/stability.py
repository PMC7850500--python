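"""Linear stability of the homogeneous state against spatial perturbations.

Each Fourier mode q of a perturbation (dc, dp_x, dp_y, dn_a, dn_i) about
the homogeneous fixpoint evolves with a 5x5 linear operator.  Its
eigenvalue with the largest real part, s_max(q), is the growth exponent of
the mode: Re s_max > 0 with Im s_max != 0 signals an oscillatory (wave)
instability, Im s_max = 0 a stationary (Turing) one.  The wavelength
lambda0 = 2 pi / |q*| of the fastest-growing mode predicts the wavelength
of the emerging pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from .homogeneous import FixpointInfo, find_fixpoint
from .params import ModelParams

Character = Literal["oscillatory", "stationary", "stable"]

#: imaginary parts below this count as zero when deciding the instability
#: character
_IM_TOL = 1e-9


@dataclass(frozen=True)
class ModeGrowth:
    """Growth exponents of a single Fourier mode."""

    q: tuple
    exponents: tuple
    s_max: complex


@dataclass(frozen=True)
class DispersionCurve:
    """Sampled dispersion relation s_max(|q|) and its summary."""

    q: np.ndarray
    re_s_max: np.ndarray
    im_s_max: np.ndarray
    lambda0: float | None
    q_peak: float | None
    character: Character


def mode_matrix(q, params: ModelParams,
                fix: FixpointInfo | None = None) -> np.ndarray:
    """Assemble the 5x5 linear operator of mode q = (q_x, q_y).

    Row/column order is (c, p_x, p_y, n_a, n_i).  The polarization couples
    to the density gradients through the -i v_a q terms; the nucleator rows
    exchange mass through the activation term (omega0 + omega n_a0^2) and
    its derivative 2 omega n_a0 n_i0, and the inactivation terms
    omega_d (c0 dn_a + n_a0 dc).  Inactive nucleators diffuse with D_i.
    """
    p = params
    if fix is None:
        fix = find_fixpoint(p)
    qx, qy = float(q[0]), float(q[1])
    q2 = qx * qx + qy * qy
    act = p.omega0 + p.omega * fix.n_a0 ** 2       # activation propensity
    dact = 2.0 * p.omega * fix.n_a0 * fix.n_i0     # its n_a derivative
    iva = 1j * p.v_a
    M = np.zeros((5, 5), dtype=complex)
    M[0, 0] = -p.k_d
    M[0, 1] = -iva * qx
    M[0, 2] = -iva * qy
    M[0, 3] = p.alpha
    M[1, 0] = -iva * qx
    M[1, 1] = -p.k_d
    M[2, 0] = -iva * qy
    M[2, 2] = -p.k_d
    M[3, 0] = -p.omega_d * fix.n_a0
    M[3, 3] = -p.D_a * q2 + dact - p.omega_d * fix.c0
    M[3, 4] = act
    M[4, 0] = p.omega_d * fix.n_a0
    M[4, 3] = -dact + p.omega_d * fix.c0
    M[4, 4] = -p.D_i * q2 - act
    return M


def mode_growth(q, params: ModelParams,
                fix: FixpointInfo | None = None) -> ModeGrowth:
    """Eigenvalues of the mode matrix, ordered by descending real part
    (ties broken by descending |imag|)."""
    if fix is None:
        fix = find_fixpoint(params)
    eig = np.linalg.eigvals(mode_matrix(q, params, fix))
    order = np.lexsort((-np.abs(eig.imag), -eig.real))
    eig = eig[order]
    return ModeGrowth(q=(float(q[0]), float(q[1])),
                      exponents=tuple(eig), s_max=complex(eig[0]))


def _s_max_re(qmag: float, params: ModelParams, fix: FixpointInfo) -> float:
    eig = np.linalg.eigvals(mode_matrix((qmag, 0.0), params, fix))
    return float(eig.real.max())


def dispersion(params: ModelParams, q_max: float = 150.0,
               n_q: int = 256,
               fix: FixpointInfo | None = None) -> DispersionCurve:
    """Sweep |q| in [0, q_max] and summarize the dispersion relation.

    The operator is isotropic (it depends on q only through q^2 and the
    rotationally covariant p couplings), so modes are sampled along the
    x-axis.  ``lambda0`` is refined by bounded scalar maximization of
    Re s_max around the coarse peak.
    """
    if n_q < 16:
        raise ValueError("n_q must be >= 16")
    if fix is None:
        fix = find_fixpoint(params)
    qs = np.linspace(0.0, q_max, n_q)
    re_s = np.empty(n_q)
    im_s = np.empty(n_q)
    for i, qm in enumerate(qs):
        g = mode_growth((qm, 0.0), params, fix)
        re_s[i] = g.s_max.real
        im_s[i] = g.s_max.imag
    # exclude the conserved q=0 zero mode when looking for an instability
    interior = slice(1, None)
    i_peak = 1 + int(np.argmax(re_s[interior]))
    if re_s[i_peak] <= 0.0:
        return DispersionCurve(q=qs, re_s_max=re_s, im_s_max=im_s,
                               lambda0=None, q_peak=None, character="stable")
    lo = qs[max(i_peak - 1, 1)]
    hi = qs[min(i_peak + 1, n_q - 1)]
    res = minimize_scalar(lambda qm: -_s_max_re(qm, params, fix),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    q_star = float(res.x)
    g_star = mode_growth((q_star, 0.0), params, fix)
    char: Character = ("oscillatory"
                       if abs(g_star.s_max.imag) > _IM_TOL else "stationary")
    return DispersionCurve(q=qs, re_s_max=re_s, im_s_max=im_s,
                           lambda0=2.0 * np.pi / q_star, q_peak=q_star,
                           character=char)


def fastest_wavelength(params: ModelParams, q_max: float = 150.0,
                       n_q: int = 256) -> float:
    """Wavelength 2 pi/|q*| of the fastest-growing mode.

    Raises RuntimeError in a linearly stable regime.
    """
    curve = dispersion(params, q_max=q_max, n_q=n_q)
    if curve.lambda0 is None:
        raise RuntimeError("no instability: homogeneous state is "
                           "linearly stable at all sampled wavenumbers")
    return curve.lambda0


def discrete_mode_growth(params: ModelParams, L: float,
                         n_max: int = 64,
                         fix: FixpointInfo | None = None):
    """Growth exponents on the discrete mode lattice q_n = 2 pi n / L of a
    finite periodic box; returns (q_n, s_max) arrays for n = 0..n_max."""
    if fix is None:
        fix = find_fixpoint(params)
    qs = 2.0 * np.pi * np.arange(n_max + 1) / L
    s = np.array([mode_growth((qm, 0.0), params, fix).s_max for qm in qs])
    return qs, s
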