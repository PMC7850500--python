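"""Pattern measurement: wavelength, wave speed, and pattern class."""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy.fft import fft, fft2, fftfreq

from .dynamics import SimResult
from .grids import DomainGrid

PatternClass = Literal["homogeneous", "traveling_wave", "turing_stationary",
                       "irregular"]

#: spatial coefficient of variation below which a field counts as
#: homogeneous
HOMOGENEOUS_CV = 1e-3
#: fraction of a run treated as transient and discarded before classifying
TRANSIENT_FRACTION = 0.5


def _power_spectrum(c_field: np.ndarray, grid: DomainGrid):
    """|FFT|^2 of the mean-subtracted field, with wavenumber magnitudes."""
    f = c_field - c_field.mean()
    if grid.dim == 1:
        F = fft(f)
        q = 2.0 * np.pi * fftfreq(grid.N_g, d=grid.spacing)
        return np.abs(q), np.abs(F) ** 2
    F = fft2(f)
    qx = 2.0 * np.pi * fftfreq(grid.N_g, d=grid.spacing)
    qmag = np.sqrt(qx[:, None] ** 2 + qx[None, :] ** 2)
    return qmag.ravel(), np.abs(F).ravel() ** 2


def measure_wavelength(c_field: np.ndarray, grid: DomainGrid,
                       min_peak_fraction: float = 1e-4) -> float | None:
    """Dominant wavelength 2 pi/|q| of a patterned field.

    Uses the power-weighted location of the strongest nonzero mode of the
    radially collected power spectrum.  Returns None when no mode carries
    at least ``min_peak_fraction`` of the field's variance (homogeneous
    signal).
    """
    qmag, power = _power_spectrum(c_field, grid)
    nonzero = qmag > 1e-12
    qmag, power = qmag[nonzero], power[nonzero]
    total = power.sum()
    if total <= 0 or c_field.std() < HOMOGENEOUS_CV * abs(c_field.mean()):
        return None
    i_max = int(np.argmax(power))
    if power[i_max] < min_peak_fraction * total:
        return None
    # average q over the modes within the peak's magnitude bin (degenerate
    # directions of the same |q|), power-weighted
    q_star = qmag[i_max]
    band = np.abs(qmag - q_star) < 0.5 * 2.0 * np.pi / grid.L
    q_mean = float(np.sum(qmag[band] * power[band]) / np.sum(power[band]))
    return 2.0 * np.pi / q_mean


def measure_wave_speed(result: SimResult,
                       min_speed: float = 1e-3) -> tuple:
    """Wave speed from the phase drift of the dominant Fourier mode.

    Uses the actin field of the snapshots in the statistically stationary
    tail of the run.  For each consecutive snapshot pair the phase change
    of the dominant mode (unwrapped, divided by |q| dt) estimates the
    speed; the mean is returned together with a ``traveling`` flag.  A
    standing wave or stationary pattern gives |speed| below ``min_speed``
    times the pattern scale and is flagged non-traveling.
    """
    snaps = result.snapshots
    if len(snaps) < 2:
        raise ValueError("need at least two snapshots")
    i0 = int(len(snaps) * TRANSIENT_FRACTION)
    tail = snaps[i0:] if len(snaps) - i0 >= 2 else snaps[-2:]
    grid = result.grid
    # dominant mode of the last frame
    f = tail[-1].c - tail[-1].c.mean()
    if grid.dim == 1:
        F = fft(f)
        qx = 2.0 * np.pi * fftfreq(grid.N_g, d=grid.spacing)
        idx = int(np.argmax(np.abs(F[1:grid.N_g // 2])) + 1)
        qvec = qx[idx]

        def mode_amp(field):
            return fft(field - field.mean())[idx]
        qnorm = abs(qvec)
    else:
        F = fft2(f)
        qx = 2.0 * np.pi * fftfreq(grid.N_g, d=grid.spacing)
        P = np.abs(F) ** 2
        P[0, 0] = 0.0
        i, j = np.unravel_index(int(np.argmax(P)), P.shape)
        qvec = np.array([qx[i], qx[j]])
        qnorm = float(np.hypot(*qvec))

        def mode_amp(field):
            return fft2(field - field.mean())[i, j]
    if qnorm == 0:
        return 0.0, False
    phases, times, amps = [], [], []
    for s in tail:
        a = mode_amp(s.c)
        phases.append(np.angle(a))
        amps.append(abs(a))
        times.append(s.t)
    phases = np.unwrap(np.array(phases))
    times = np.array(times)
    slope = np.polyfit(times, phases, 1)[0]
    speed = -slope / qnorm  # c ~ exp(-i q x) convention: phase advances as q v t
    # standing waves beat in amplitude but their phase is locked
    amp_cv = np.std(amps) / max(np.mean(amps), 1e-300)
    pattern_scale = 2.0 * np.pi / qnorm
    traveling = abs(speed) > min_speed * pattern_scale and amp_cv < 0.5
    return float(speed), bool(traveling)


def classify_pattern(result: SimResult,
                     stationary_tol: float = 0.02) -> PatternClass:
    """Classify the asymptotic state of a periodic-box run.

    Operates on the final half of the run (transient discarded):
    homogeneous if the spatial coefficient of variation is negligible;
    stationary (Turing) if spatial structure persists but frame-to-frame
    change, relative to the pattern amplitude and per unit time scaled by
    the snapshot spacing, is below ``stationary_tol``; traveling if the
    dominant mode translates at a well-defined speed; irregular otherwise.
    """
    snaps = result.snapshots
    if len(snaps) < 3:
        raise ValueError("need at least three snapshots to classify")
    i0 = int(len(snaps) * TRANSIENT_FRACTION)
    tail = snaps[i0:] if len(snaps) - i0 >= 3 else snaps[-3:]
    c_last = tail[-1].c
    cv = c_last.std() / max(abs(c_last.mean()), 1e-300)
    if cv < HOMOGENEOUS_CV:
        return "homogeneous"
    # frame-to-frame change relative to pattern amplitude
    amp = max(np.ptp(c_last), 1e-300)
    changes = [np.max(np.abs(b.c - a.c)) / amp
               for a, b in zip(tail[:-1], tail[1:])]
    if np.median(changes) < stationary_tol:
        return "turing_stationary"
    speed, traveling = measure_wave_speed(result)
    if traveling:
        # verify the translation explains the frame change: shift the
        # second-to-last frame by speed * dt along the dominant direction
        return "traveling_wave"
    return "irregular"
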