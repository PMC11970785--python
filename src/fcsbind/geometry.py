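"""Observation-volume geometry and concentration arithmetic.

The two-photon excitation volume is approximated by a 3-D Gaussian
detection profile

    MDE(x, y, z) = exp(-2 (x^2 + y^2) / w0^2 - 2 z^2 / z0^2),

where ``w0`` and ``z0`` are the lateral and axial distances at which the
intensity falls to 1/e^2 of its peak.  The conventional effective volume
for this profile is V_eff = pi^{3/2} w0^2 z0; the number of molecules N
reported by an FCS fit refers to this volume, so the molar concentration
follows as c = N / (N_A V_eff).

Units are fixed package-wide: lengths in um, times in s, diffusion in
um^2/s, rates in 1/s, concentrations in mol/L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

AVOGADRO = 6.02214076e23  # 1/mol
_UM3_TO_L = 1e-15

#: supported effective-volume conventions
VOLUME_CONVENTIONS = ("pi32",)


@dataclass(frozen=True)
class ObservationVolume:
    """Gaussian observation-volume geometry.

    Parameters
    ----------
    w0 : float
        Lateral 1/e^2 radius in um.
    z0 : float
        Axial 1/e^2 extent in um.
    volume_convention : str
        Effective-volume convention; only ``"pi32"``
        (V_eff = pi^{3/2} w0^2 z0) is implemented.
    """

    w0: float = 0.22
    z0: float = 0.6
    volume_convention: str = "pi32"

    def __post_init__(self) -> None:
        if self.w0 <= 0 or self.z0 <= 0:
            raise ValueError(f"w0 and z0 must be positive, got w0={self.w0}, z0={self.z0}")
        if self.volume_convention not in VOLUME_CONVENTIONS:
            raise ValueError(
                f"unknown volume convention {self.volume_convention!r}; "
                f"supported: {VOLUME_CONVENTIONS}"
            )
        if self.z0 < self.w0:
            warnings.warn(
                f"z0={self.z0} um < w0={self.w0} um: axial extent smaller than "
                "lateral waist is unusual for a focused beam",
                stacklevel=3,
            )

    @property
    def aspect(self) -> float:
        """Axial-to-lateral aspect ratio z0/w0."""
        return self.z0 / self.w0

    def effective_volume_um3(self) -> float:
        return float(3.141592653589793 ** 1.5 * self.w0**2 * self.z0)

    def effective_volume_L(self) -> float:
        return self.effective_volume_um3() * _UM3_TO_L


def effective_volume(volume: ObservationVolume) -> float:
    """Effective observation volume in litres (pi32 convention)."""
    return volume.effective_volume_L()


def concentration_from_n(n_molecules: float, volume: ObservationVolume) -> float:
    """Molar concentration (mol/L) of ``n_molecules`` in the effective volume."""
    if n_molecules <= 0:
        raise ValueError(f"N must be positive, got {n_molecules}")
    return n_molecules / (AVOGADRO * effective_volume(volume))


def kon_star_to_kon(kon_star: float, n_molecules: float, volume: ObservationVolume) -> float:
    """Convert a pseudo-first-order association rate kon* (1/s) to kon (1/M/s).

    kon = kon* / c where c is the concentration corresponding to
    ``n_molecules`` in the effective volume.  The round trip
    ``kon * c == kon*`` is exact to floating point.
    """
    if kon_star < 0:
        raise ValueError(f"kon_star must be non-negative, got {kon_star}")
    return kon_star / concentration_from_n(n_molecules, volume)


def kon_to_kon_star(kon: float, n_molecules: float, volume: ObservationVolume) -> float:
    """Inverse of :func:`kon_star_to_kon`."""
    if kon < 0:
        raise ValueError(f"kon must be non-negative, got {kon}")
    return kon * concentration_from_n(n_molecules, volume)


@dataclass(frozen=True)
class BindingDiffusionParams:
    """The four fitted parameters of the diffusion-plus-binding model.

    N : molecules in the observation volume
    D : diffusion coefficient, um^2/s
    kon_star : pseudo-first-order association rate, 1/s
    koff : dissociation rate, 1/s
    """

    N: float
    D: float
    kon_star: float
    koff: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError(f"N must be positive, got {self.N}")
        if self.D < 0:
            raise ValueError(f"D must be non-negative, got {self.D}")
        if self.kon_star < 0:
            raise ValueError(f"kon_star must be non-negative, got {self.kon_star}")
        if self.koff <= 0:
            raise ValueError(f"koff must be positive, got {self.koff}")

    @property
    def bound_fraction(self) -> float:
        """Stationary bound fraction kon*/(kon* + koff)."""
        if self.kon_star == 0:
            return 0.0
        return self.kon_star / (self.kon_star + self.koff)


def stokes_einstein_scale(d_ref: float, t_ref_c: float, t_target_c: float,
                          eta_ratio: float | None = None) -> float:
    """Rescale a diffusion coefficient between temperatures.

    D ~ T/eta (Stokes-Einstein).  If ``eta_ratio`` (eta_target/eta_ref) is not
    given, the viscosity of water is approximated by the Vogel equation
    eta(T) = A exp(B / (T - C)) with A=2.414e-5 Pa s, B=247.8 K, C=140 K.

    Useful when a reference dye's D is tabulated at a different temperature
    than the measurement (e.g. a 37 C literature value used at 22 C room
    temperature).
    """
    if d_ref <= 0:
        raise ValueError("reference D must be positive")
    t_ref = t_ref_c + 273.15
    t_target = t_target_c + 273.15
    if eta_ratio is None:
        def eta(t: float) -> float:
            return 2.414e-5 * 10 ** (247.8 / (t - 140.0))
        eta_ratio = eta(t_target) / eta(t_ref)
    return d_ref * (t_target / t_ref) / eta_ratio
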