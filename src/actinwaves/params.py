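"""Model parameters, physical scales, and unit conversion.

All quantities are nondimensional unless stated otherwise: time is measured
in units of the inverse spontaneous nucleator-activation rate (1/omega_0) and
length in units of the diffusion length of inactive nucleators,
sqrt(D_i/omega_0).  After this scaling omega_0 = 1 and D_i = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional parameters of the actin-nucleator dynamics.

    Defaults are the working parameter set of the model: actin turnover is
    fast (k_d, alpha >> 1) while nucleator activation sets the unit time
    scale.  ``v_a`` and ``omega_d`` are the two control parameters swept in
    most analyses; ranges roughly [0.1, 0.6] each.

    Attributes
    ----------
    D_a : float
        Diffusion constant of active (membrane/filament-bound) nucleators.
    D_i : float
        Diffusion constant of inactive (cytosolic) nucleators; 1 after
        nondimensionalization.
    v_a : float
        Effective actin polymerization speed.
    k_d : float
        Effective actin filament degradation rate (also damps polarization).
    omega0 : float
        Spontaneous nucleator activation rate; 1 after scaling.
    omega : float
        Cooperative (autocatalytic) activation strength.
    omega_d : float
        Rate of actin-induced nucleator inactivation.
    alpha : float
        Nucleation rate of new actin by active nucleators.
    n_tot : float
        Mean total nucleator density (conserved).
    """

    D_a: float = 4e-2
    D_i: float = 1.0
    v_a: float = 0.4
    k_d: float = 176.0
    omega0: float = 1.0
    omega: float = 6e-3
    omega_d: float = 0.35
    alpha: float = 588.0
    n_tot: float = 700.0

    def __post_init__(self) -> None:
        for name in ("D_a", "D_i", "v_a", "k_d", "omega0", "omega",
                     "omega_d", "alpha", "n_tot"):
            val = getattr(self, name)
            if not val >= 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if not self.D_i > 0:
            raise ValueError("D_i must be > 0")
        if not self.n_tot > 0:
            raise ValueError("n_tot must be > 0")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PhysicalScales:
    """Conversion between nondimensional and physical units.

    ``time_unit`` is 1/omega_0 in seconds; ``length_unit`` is
    sqrt(D_i/omega_0) in micrometers.  Defaults match immature dendritic
    cells (slow amoeboid migrators).
    """

    time_unit: float = 91.6     # seconds per nondim time unit
    length_unit: float = 63.5   # micrometers per nondim length unit

    def __post_init__(self) -> None:
        if not (self.time_unit > 0 and self.length_unit > 0):
            raise ValueError("scales must be positive")


#: Physical dimension of each convertible quantity, as powers of
#: (length_unit, time_unit).
_KIND_POWERS = {
    "length": (1, 0),
    "time": (0, 1),
    "speed": (1, -1),
    "diffusion": (2, -1),
}


def to_physical_units(quantity: float, kind: str,
                      scales: PhysicalScales = PhysicalScales()) -> float:
    """Convert a nondimensional quantity to physical units.

    ``kind`` is one of 'length' (um), 'time' (s), 'speed' (um/s) or
    'diffusion' (um^2/s).
    """
    try:
        lp, tp = _KIND_POWERS[kind]
    except KeyError:
        raise ValueError(
            f"unknown kind {kind!r}; expected one of {sorted(_KIND_POWERS)}"
        ) from None
    return quantity * scales.length_unit ** lp * scales.time_unit ** tp


def from_physical_units(quantity: float, kind: str,
                        scales: PhysicalScales = PhysicalScales()) -> float:
    """Inverse of :func:`to_physical_units`."""
    try:
        lp, tp = _KIND_POWERS[kind]
    except KeyError:
        raise ValueError(
            f"unknown kind {kind!r}; expected one of {sorted(_KIND_POWERS)}"
        ) from None
    return quantity / (scales.length_unit ** lp * scales.time_unit ** tp)


@dataclass(frozen=True)
class PhaseFieldParams:
    """Parameters of the phase-field (cell membrane) dynamics.

    The phase field Psi is ~1 inside the cell and ~0 outside; its 0.5 level
    set is the membrane.

    Attributes
    ----------
    D_psi : float
        Interfacial-tension (surface tension) coefficient.
    kappa : float
        Strength of the double-well free energy; sets interface sharpness
        and relaxation speed.
    epsilon : float
        Stiffness of the soft area constraint.
    beta : float
        Coupling of actin polarization to the membrane (protrusive force).
    A_0 : float
        Target cell area.
    """

    D_psi: float = 5e-3
    kappa: float = 118.0
    epsilon: float = 8.0
    beta: float = 5.75e-3
    A_0: float = 0.083

    def __post_init__(self) -> None:
        for name in ("D_psi", "kappa", "epsilon", "beta", "A_0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **changes) -> "PhaseFieldParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)
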