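"""Periodic domains and Fourier (pseudo-spectral) differentiation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.fft import rfftfreq, fftfreq
from scipy.fft import irfft, irfft2, rfft, rfft2


@dataclass(frozen=True)
class DomainGrid:
    """Uniform periodic grid: side length L, N_g points per axis, dim 1 or 2.

    N_g must be a power of two (FFT efficiency).
    """

    L: float
    N_g: int
    dim: int = 2

    def __post_init__(self) -> None:
        if self.dim not in (1, 2):
            raise ValueError("dim must be 1 or 2")
        if self.N_g < 4 or (self.N_g & (self.N_g - 1)) != 0:
            raise ValueError("N_g must be a power of two >= 4")
        if not self.L > 0:
            raise ValueError("L must be > 0")

    @property
    def spacing(self) -> float:
        return self.L / self.N_g

    @property
    def shape(self) -> tuple:
        return (self.N_g,) * self.dim

    @property
    def cell_volume(self) -> float:
        return self.spacing ** self.dim

    def coords(self):
        """Coordinate array(s): x for 1-D, (x, y) meshgrid for 2-D
        (indexing='ij': axis 0 is x)."""
        x = np.arange(self.N_g) * self.spacing
        if self.dim == 1:
            return x
        return np.meshgrid(x, x, indexing="ij")

    def integrate(self, f: np.ndarray) -> float:
        """Trapezoid = Riemann sum on a periodic grid."""
        return float(f.sum() * self.cell_volume)


class SpectralOps:
    """Cached wavenumbers and FFT-based differential operators for a grid.

    Real fields, rfft along the last axis.  Provides first derivatives,
    the Laplacian, diffusion propagators exp(-D q^2 dt) and a 2/3-rule
    dealiasing filter.
    """

    def __init__(self, grid: DomainGrid):
        self.grid = grid
        n, L = grid.N_g, grid.L
        k1 = 2.0 * np.pi * rfftfreq(n, d=L / n)          # last axis (rfft)
        if grid.dim == 1:
            self.ikx = 1j * k1
            self.q2 = k1 ** 2
            self.dealias_mask = (np.abs(k1) <= 2.0 / 3.0 * np.pi * n / L)
        else:
            kx = 2.0 * np.pi * fftfreq(n, d=L / n)[:, None]  # first axis
            ky = k1[None, :]
            self.ikx = 1j * kx
            self.iky = 1j * ky
            self.q2 = kx ** 2 + ky ** 2
            kmax = 2.0 / 3.0 * np.pi * n / L
            self.dealias_mask = (np.abs(kx) <= kmax) & (np.abs(ky) <= kmax)

    # -- transforms -------------------------------------------------------
    def fwd(self, f):
        return rfft(f) if self.grid.dim == 1 else rfft2(f)

    def inv(self, F):
        n = self.grid.N_g
        return irfft(F, n=n) if self.grid.dim == 1 else irfft2(F, s=(n, n))

    # -- derivatives ------------------------------------------------------
    def dx(self, f):
        return self.inv(self.ikx * self.fwd(f))

    def dy(self, f):
        if self.grid.dim == 1:
            raise ValueError("dy undefined on a 1-D grid")
        return self.inv(self.iky * self.fwd(f))

    def laplacian(self, f):
        return self.inv(-self.q2 * self.fwd(f))

    def divergence(self, fx, fy=None):
        """div of a vector field; fy omitted in 1-D."""
        if self.grid.dim == 1:
            return self.inv(self.ikx * self.fwd(fx))
        return self.inv(self.ikx * self.fwd(fx) + self.iky * self.fwd(fy))

    def dealias(self, f):
        """Remove the top third of the spectrum (2/3 rule) from a real
        field; used on nonlinear products."""
        return self.inv(self.fwd(f) * self.dealias_mask)

    def diffuse(self, f, D: float, dt: float):
        """Apply the exact diffusion propagator exp(-D q^2 dt)."""
        if D == 0.0 or dt == 0.0:
            return f
        return self.inv(self.fwd(f) * np.exp(-D * self.q2 * dt))
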