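"""Deterministic Förster-theory primitives.

Transfer rates, efficiencies, Förster radius, spectral overlap, the dipole
orientation factor, and dark-state (blinking) scaling relations.  All
numeric operations accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd

ArrayLike = Union[float, np.ndarray]

#: Numerical prefactor in the Förster-radius formula when the overlap
#: integral J is expressed in nm^4 cm^2 / mmole and R0 in nm.
R0_PREFACTOR = 0.02108

#: Dynamic random isotropic average of the orientation factor.
KAPPA2_ISOTROPIC = 2.0 / 3.0


@dataclass(frozen=True)
class ForsterSystem:
    """Photophysical parameter bundle for one donor-acceptor pair type.

    Parameters
    ----------
    tau0D : float
        Donor excited-state lifetime in the absence of acceptor (ns).
    R0 : float
        Förster distance (nm); contains the assumed orientation factor.
    refractive_index : float
        Refractive index of the intervening medium.
    QD : float
        Donor fluorescence quantum yield in the absence of acceptor.
    regime : {"dynamic", "static"}
        Orientational averaging regime tag.
    """

    tau0D: float
    R0: float
    refractive_index: float = 1.33
    QD: float = 1.0
    regime: Literal["dynamic", "static"] = "dynamic"

    def __post_init__(self) -> None:
        if self.tau0D <= 0:
            raise ValueError(f"tau0D must be > 0, got {self.tau0D}")
        if self.R0 < 0:
            raise ValueError(f"R0 must be >= 0, got {self.R0}")
        if not 0.0 <= self.QD <= 1.0:
            raise ValueError(f"QD must be in [0, 1], got {self.QD}")
        if self.refractive_index < 1.0:
            raise ValueError(
                f"refractive_index must be >= 1, got {self.refractive_index}"
            )
        if self.regime not in ("dynamic", "static"):
            raise ValueError(f"regime must be 'dynamic' or 'static', got {self.regime!r}")


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: donor emission or acceptor molar extinction.

    Wavelengths are in nm and must be strictly increasing; values are
    non-negative (emission intensity per unit wavelength, or extinction
    coefficient in cm^-1 per mmole-consistent units).
    """

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vv = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vv)
        if wl.ndim != 1 or vv.ndim != 1 or wl.size != vv.size:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(vv < 0):
            raise ValueError("spectrum values must be non-negative")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "Spectrum":
        """Read a two-column ``wavelength_nm,value`` CSV (header required)."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False)

    def interpolate(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation; zero outside the spectrum's support."""
        return np.interp(wavelengths, self.wavelengths, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class DarkStateParams:
    """Fractions of donors/acceptors occupying a non-absorbing dark state."""

    f_dark_acceptor: float = 0.0
    f_dark_donor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("f_dark_acceptor", "f_dark_donor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def efficiency_from_distance(R_DA: ArrayLike, system: ForsterSystem) -> ArrayLike:
    """FRET efficiency of a fixed pair at separation ``R_DA``.

    E = 1 / (1 + (R_DA / R0)^6); strictly decreasing in R_DA with
    E(R0) = 0.5 exactly.
    """
    r = np.asarray(R_DA, dtype=float)
    if np.any(r <= 0):
        raise ValueError("R_DA must be > 0")
    if system.R0 <= 0:
        raise ValueError("system.R0 must be > 0")
    out = 1.0 / (1.0 + (r / system.R0) ** 6)
    return float(out) if np.isscalar(R_DA) else out


def transfer_rate(R_DA: ArrayLike, system: ForsterSystem) -> ArrayLike:
    """Energy-transfer rate constant k_T = (1/tau0D) (R0/R_DA)^6 in ns^-1."""
    r = np.asarray(R_DA, dtype=float)
    if np.any(r <= 0):
        raise ValueError("R_DA must be > 0")
    out = (system.R0 / r) ** 6 / system.tau0D
    return float(out) if np.isscalar(R_DA) else out


def efficiency_from_rate(k_T: ArrayLike, tau0D: float) -> ArrayLike:
    """Efficiency from a transfer rate: E = k_T / (k_T + 1/tau0D)."""
    if tau0D <= 0:
        raise ValueError("tau0D must be > 0")
    k = np.asarray(k_T, dtype=float)
    if np.any(k < 0):
        raise ValueError("k_T must be >= 0")
    out = k / (k + 1.0 / tau0D)
    return float(out) if np.isscalar(k_T) else out


def forster_radius(QD: float, J: float, n: float, kappa2: float) -> float:
    """Förster distance in nm.

    R0 = [0.02108 * kappa2 * QD * n^-4 * J]^(1/6) with J in
    nm^4 cm^2 / mmole.  Returns 0 when any of kappa2, QD or J is 0.
    """
    if n < 1.0:
        raise ValueError(f"refractive index must be >= 1, got {n}")
    if QD < 0 or J < 0 or kappa2 < 0:
        raise ValueError("QD, J and kappa2 must be >= 0")
    return float((R0_PREFACTOR * kappa2 * QD * J / n**4) ** (1.0 / 6.0))


def overlap_integral(donor_emission: Spectrum, acceptor_extinction: Spectrum) -> float:
    """Spectral overlap integral J in nm^4 cm^2 / mmole.

    J = ∫ f_D(λ) ε_A(λ) λ^4 dλ / ∫ f_D(λ) dλ, evaluated by trapezoidal
    quadrature on the union wavelength grid restricted to the common range.
    The denominator normalises over the donor's full support, so J is
    invariant under positive rescaling of the donor spectrum.  Returns 0
    when the spectra do not overlap in wavelength.
    """
    donor_total = float(np.trapezoid(donor_emission.values, donor_emission.wavelengths))
    if donor_total <= 0:
        raise ValueError("donor emission spectrum integrates to zero")

    lo = max(donor_emission.wavelengths[0], acceptor_extinction.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1], acceptor_extinction.wavelengths[-1])
    if lo >= hi:
        return 0.0

    grid = np.union1d(donor_emission.wavelengths, acceptor_extinction.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    fd = donor_emission.interpolate(grid)
    ea = acceptor_extinction.interpolate(grid)
    numerator = float(np.trapezoid(fd * ea * grid**4, grid))
    return numerator / donor_total


def kappa_squared(theta: ArrayLike, omega: ArrayLike) -> ArrayLike:
    """Dipole orientation factor from the two characteristic angles.

    kappa^2 = cos^2(omega) * (1 + 3 cos^2(theta)), bounded in [0, 4].
    ``theta`` is the angle between the donor emission dipole and the
    donor-acceptor separation vector; ``omega`` the angle between the
    acceptor absorption dipole and the donor's electric field.
    """
    ct2 = np.cos(theta) ** 2
    co2 = np.cos(omega) ** 2
    out = co2 * (1.0 + 3.0 * ct2)
    if np.isscalar(theta) and np.isscalar(omega):
        return float(out)
    return out


def blinking_mean_efficiency(E_mean: float, f_dark_acceptor: float) -> float:
    """Population mean efficiency under acceptor blinking.

    <E_B> = (1 - F_D) * <E>: dark acceptors cannot receive transfer, adding
    a zero-efficiency subpopulation that scales the mean by the bright
    fraction.
    """
    if not 0.0 <= E_mean <= 1.0:
        raise ValueError(f"E_mean must be in [0, 1], got {E_mean}")
    if not 0.0 <= f_dark_acceptor <= 1.0:
        raise ValueError(f"f_dark_acceptor must be in [0, 1], got {f_dark_acceptor}")
    return (1.0 - f_dark_acceptor) * E_mean


def r0_attenuation(params: DarkStateParams) -> float:
    """Multiplicative attenuation of the apparent R0 due to dark states.

    Dark donors depress the measured quantum yield and dark acceptors the
    measured extinction coefficient (hence J); each enters R0 through a
    sixth root, giving [(1 - f_Dd)(1 - f_Ad)]^(1/6).

    Note: this closed form is inferred from the R0 formula with QD and J
    each scaled by the bright fraction; it is monotone decreasing in both
    fractions and equals 1 when both are zero.
    """
    return float(
        ((1.0 - params.f_dark_donor) * (1.0 - params.f_dark_acceptor)) ** (1.0 / 6.0)
    )
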