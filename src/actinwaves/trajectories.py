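"""Persistent-random-walk statistics of cell-center trajectories.

Amoeboid trajectories are persistent random walks (PRW): the velocity
decorrelates over a persistence time tau, giving the mean squared
displacement

    msd(t) = 4 D t + 2 (v tau)^2 (e^(-t/tau) - 1),

with effective diffusion constant D and persistent speed v.  This module
estimates the MSD from single tracks, fits the PRW model, measures
instantaneous speeds, classifies trajectories (stationary / diffusive /
straight-segment / curved-segment random walk), and generates synthetic
PRW tracks with known (D, v, tau) for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

MigrationClass = Literal["stationary", "diffusive", "straight_segment_rw",
                         "curved_segment_rw"]


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged mean squared displacement of one trajectory."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray


@dataclass(frozen=True)
class PRWFit:
    """Fitted persistent-random-walk parameters."""

    D: float
    v: float
    tau: float
    cov: np.ndarray | None
    rms_residual: float
    pure_diffusion: bool      # True when the tau = 0 submodel was selected
    converged: bool = True


def msd(positions: np.ndarray, times: np.ndarray | None = None,
        max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD over all start points for each lag.

    ``positions`` is (n, d); sampling must be uniform (``times`` is used
    for the lag axis and checked for uniformity).  Lags run up to
    ``max_lag_fraction`` of the duration.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n < 100:
        raise ValueError("trajectory too short (need >= 100 samples)")
    if times is None:
        dt = 1.0
    else:
        steps = np.diff(times)
        if np.max(np.abs(steps - steps[0])) > 1e-6 * abs(steps[0]):
            raise ValueError("MSD estimator requires uniform sampling")
        dt = float(steps[0])
    max_lag = max(int(n * max_lag_fraction), 1)
    lags = np.arange(1, max_lag + 1)
    out = np.empty(max_lag)
    npairs = np.empty(max_lag, dtype=int)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        out[i] = np.mean(np.sum(d * d, axis=1))
        npairs[i] = d.shape[0]
    return MSDCurve(lags=lags * dt, msd=out, n_pairs=npairs)


def prw_msd(t, D, v, tau):
    """The PRW MSD law; continuous in the tau -> 0 limit (pure diffusion)."""
    t = np.asarray(t, dtype=float)
    if tau <= 0:
        return 4.0 * D * t
    return 4.0 * D * t + 2.0 * (v * tau) ** 2 * (np.expm1(-t / tau))


def fit_prw(curve: MSDCurve) -> PRWFit:
    """Weighted least-squares fit of the PRW law to an MSD curve.

    Long lags are de-emphasized: the sampling error of a time-averaged
    MSD grows with its value and with the lag (fewer effectively
    independent pairs), so sigma ~ msd * sqrt(lag / n_pairs).  tau is
    multi-started over the lag range; when the full model does not beat
    the pure-diffusion submodel by a small-sample information criterion
    (2-point penalty per extra parameter) the fit is pinned to tau = 0.
    """
    t = curve.lags
    y = curve.msd
    scale = max(y.max(), 1e-300)
    sigma = np.maximum(y, 1e-6 * scale) \
        * np.sqrt(t / (np.maximum(curve.n_pairs, 1) * t[0]))

    # pure-diffusion submodel: weighted linear fit through the origin
    w = 1.0 / sigma ** 2
    D_lin = max(float(np.sum(w * t * y) / np.sum(w * t * t) / 4.0), 0.0)
    rss_lin = float(np.sum(w * (y - 4.0 * D_lin * t) ** 2))

    best = None
    for tau0 in np.geomspace(t[0], t[-1], 6):
        v0 = np.sqrt(max(y[-1], scale * 1e-6) / max(t[-1] * tau0, 1e-300))
        for p0 in ([D_lin if D_lin > 0 else scale / t[-1], v0, tau0],):
            try:
                popt, pcov = curve_fit(
                    prw_msd, t, y, p0=p0, sigma=sigma,
                    bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
                    maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            resid = (y - prw_msd(t, *popt)) / sigma
            rss = float(np.sum(resid ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss, pcov)
    n = len(t)
    if best is None:
        return PRWFit(D=D_lin, v=0.0, tau=0.0, cov=None,
                      rms_residual=np.sqrt(rss_lin / n),
                      pure_diffusion=True, converged=False)
    popt, rss, pcov = best
    # information criterion: n log(RSS/n) + 2k, submodel has 2 fewer params
    aic_full = n * np.log(max(rss, 1e-300) / n) + 2.0 * 3
    aic_lin = n * np.log(max(rss_lin, 1e-300) / n) + 2.0 * 1
    if aic_lin <= aic_full:
        return PRWFit(D=D_lin, v=0.0, tau=0.0, cov=None,
                      rms_residual=np.sqrt(rss_lin / n), pure_diffusion=True)
    return PRWFit(D=float(popt[0]), v=float(popt[1]), tau=float(popt[2]),
                  cov=pcov, rms_residual=np.sqrt(rss / n),
                  pure_diffusion=False)


def instantaneous_speed(positions: np.ndarray, times: np.ndarray,
                        smoothing_window: int = 5) -> float:
    """Mean instantaneous speed |dr|/dt after centered moving-average
    smoothing of the track (uniform sampling assumed)."""
    pos = np.asarray(positions, dtype=float)
    dt = float(times[1] - times[0])
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        pos = np.column_stack([
            np.convolve(pos[:, k], kernel, mode="valid")
            for k in range(pos.shape[1])])
    d = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return float(np.mean(d) / dt)


# ---------------------------------------------------------------------------
# trajectory classification

#: minimum run of samples forming a persistent segment
SEGMENT_MIN_SAMPLES = 20
#: maximum per-sample turning rate (radians) inside a persistent segment
SEGMENT_MAX_TURN = 0.2
#: speed factor over the diffusive baseline (5th percentile of step
#: lengths) required inside a segment
SEGMENT_SPEED_FACTOR = 3.0
#: total coherent turning (radians) over a segment above which it counts
#: as curved rather than straight
CURVED_TOTAL_TURN = 0.5
#: a track whose overall span stays below this multiple of the typical
#: per-frame jitter counts as stationary
STATIONARY_SPAN_FACTOR = 5.0


def _segments(speeds: np.ndarray, turns: np.ndarray,
              baseline: float) -> list:
    """Indices of persistent segments: runs of >= SEGMENT_MIN_SAMPLES with
    small turning rate and super-diffusive speed."""
    ok = (np.abs(turns) < SEGMENT_MAX_TURN) \
        & (speeds[1:] > SEGMENT_SPEED_FACTOR * baseline)
    segs = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= SEGMENT_MIN_SAMPLES:
                segs.append((start, i))
            start = None
    if start is not None and len(ok) - start >= SEGMENT_MIN_SAMPLES:
        segs.append((start, len(ok)))
    return segs


def classify_migration(positions: np.ndarray,
                       times: np.ndarray | None = None,
                       stationary_scale: float | None = None
                       ) -> MigrationClass:
    """Rule-based migration classifier.

    stationary -- the track's overall span stays within jitter (or below
    ``stationary_scale`` when given, e.g. a fraction of the cell radius);
    otherwise persistent segments (long runs of low turning rate at
    super-diffusive speed) are detected: none -> diffusive; segments are
    called curved when their accumulated signed turning is both large
    (> CURVED_TOTAL_TURN) and statistically coherent, straight otherwise.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n < 1000:
        raise ValueError("classification needs >= 1000 samples")
    steps = np.diff(pos, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    path = step_len.sum()
    span = np.max(np.linalg.norm(pos - pos.mean(axis=0), axis=1))
    jitter = np.median(step_len)
    threshold = stationary_scale if stationary_scale is not None \
        else STATIONARY_SPAN_FACTOR * jitter
    if path <= 0 or span < threshold:
        return "stationary"
    # turning angle between consecutive steps (0 where a step is zero)
    valid = step_len > 1e-12
    ang = np.zeros(len(steps))
    ang[valid] = np.arctan2(steps[valid, 1], steps[valid, 0])
    turns = np.diff(ang)
    turns = (turns + np.pi) % (2.0 * np.pi) - np.pi
    baseline = np.percentile(step_len, 5)
    segs = _segments(step_len, turns, baseline)
    covered = sum(b - a for a, b in segs)
    if not segs or covered < 0.05 * len(steps):
        return "diffusive"
    n_curved = 0
    for a, b in segs:
        seg_turns = turns[a:max(b - 1, a + 1)]
        if len(seg_turns) < 2:
            continue
        total = abs(np.sum(seg_turns))
        noise = np.std(seg_turns) * np.sqrt(len(seg_turns))
        if total > CURVED_TOTAL_TURN and total > 2.0 * noise:
            n_curved += 1
    if n_curved >= max(1, len(segs) / 2):
        return "curved_segment_rw"
    return "straight_segment_rw"


# ---------------------------------------------------------------------------
# synthetic trajectory generators

def synth_prw(D: float, v: float, tau: float, n_steps: int, dt: float,
              seed: int | None = None) -> tuple:
    """Synthetic PRW: Ornstein-Uhlenbeck velocity plus white positional
    noise, matching the PRW MSD law in ensemble average.

    The OU velocity has relaxation time tau and stationary speed scale v
    (per-component variance v^2/2), contributing 4 (v^2 tau / 2) t + 2
    (v tau)^2 (e^(-t/tau) - 1) to the MSD; independent white noise adds
    4 D0 t with D0 = D - v^2 tau / 2, which requires D >= v^2 tau/2 (the
    Fuerth value).  Returns (times, positions).
    """
    if min(D, v, tau) < 0 or n_steps < 1 or dt <= 0:
        raise ValueError("parameters must be nonnegative, n_steps >= 1, "
                         "dt > 0")
    D0 = D - v * v * tau / 2.0
    if D0 < -1e-12 * max(D, 1.0):
        raise ValueError("D must be >= v^2 tau / 2 (the persistent "
                         "contribution already exceeds the target D)")
    D0 = max(D0, 0.0)
    rng = np.random.default_rng(seed)
    times = np.arange(n_steps + 1) * dt
    if tau > 0 and v > 0:
        # exact OU update: v' = a v + b xi, a = exp(-dt/tau)
        a = np.exp(-dt / tau)
        sig = v / np.sqrt(2.0)                    # per-component std
        b = sig * np.sqrt(1.0 - a * a)
        vel = np.empty((n_steps + 1, 2))
        vel[0] = rng.normal(0.0, sig, 2)
        noise = rng.normal(0.0, 1.0, (n_steps, 2))
        for i in range(n_steps):
            vel[i + 1] = a * vel[i] + b * noise[i]
        # trapezoidal integration keeps the discrete MSD close to the law
        disp = 0.5 * (vel[:-1] + vel[1:]) * dt
    else:
        disp = np.zeros((n_steps, 2))
    if D0 > 0:
        disp = disp + rng.normal(0.0, np.sqrt(2.0 * D0 * dt), (n_steps, 2))
    pos = np.vstack([np.zeros(2), np.cumsum(disp, axis=0)])
    return times, pos


def synth_run_tumble(speed: float, run_time: float, n_steps: int,
                     dt: float, seed: int | None = None,
                     turn_rate: float = 0.0,
                     tumble_diffusion: float = 0.0,
                     tumble_time: float | None = None) -> tuple:
    """Run-and-tumble track: straight (or, with ``turn_rate``, circular)
    runs of exponential duration separated by tumbles that pick a fresh
    uniform direction.  During tumbles the walker diffuses with
    ``tumble_diffusion``.  Returns (times, positions)."""
    if tumble_time is None:
        tumble_time = 0.2 * run_time
    rng = np.random.default_rng(seed)
    times = np.arange(n_steps + 1) * dt
    pos = np.zeros((n_steps + 1, 2))
    phase_run = True
    t_left = rng.exponential(run_time)
    theta = rng.uniform(0.0, 2.0 * np.pi)
    handed = 1.0
    for i in range(n_steps):
        if phase_run:
            step = speed * dt * np.array([np.cos(theta), np.sin(theta)])
            theta += handed * turn_rate * dt
        else:
            step = rng.normal(0.0, np.sqrt(2.0 * tumble_diffusion * dt), 2)
        pos[i + 1] = pos[i] + step
        t_left -= dt
        if t_left <= 0.0:
            phase_run = not phase_run
            if phase_run:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                handed = rng.choice([-1.0, 1.0])
                t_left = rng.exponential(run_time)
            else:
                t_left = rng.exponential(tumble_time)
    return times, pos
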