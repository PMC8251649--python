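"""Optical constants of the media in the incubation chamber.

All media are described by a complex refractive index under the
``e^{+j omega t}`` phasor convention,

    n = n' - j n'',   n' > 0,  n'' >= 0,

so that a forward wave ``exp(-j k0 n z)`` decays in its direction of
propagation.  The imaginary index is tied to the absorption coefficient
``mu_a`` (exponential intensity decay rate, m^-1) by

    mu_a = 4 pi n'' / lambda0.

Tabulated constants for air, saline solution (modeled as pure water; the
solute molarities are low enough that the NIR index is indistinguishable
from water's) and borosilicate glass are provided at the three laser lines
used in photobiomodulation work on isolated mitochondria: 808, 980 and
1064 nm.  No chromatic interpolation is performed between these points;
dispersion over each narrow laser line is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "Medium",
    "Permittivity",
    "SUPPORTED_WAVELENGTHS",
    "absorption_to_imag_index",
    "imag_index_to_absorption",
    "medium_lookup",
    "mitochondrion_medium",
    "permittivity",
    "permittivity_to_index",
]

#: Wavelengths (m) at which tabulated constants exist.
SUPPORTED_WAVELENGTHS = (808e-9, 980e-9, 1064e-9)

# Mitochondria behave, for NIR scattering purposes, as homogeneous
# ellipsoids of effective index n'_m in [1.35, 1.45] and absorption
# coefficient mu_a,m in [20, 150] m^-1; the same ranges are used at all
# three wavelengths.
MITO_N_REAL_RANGE = (1.35, 1.45)
MITO_MU_A_RANGE = (20.0, 150.0)


def absorption_to_imag_index(mu_a: float, lambda0: float) -> float:
    """Imaginary refractive index n'' from absorption coefficient mu_a.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (m^-1), >= 0.
    lambda0 : float
        Vacuum wavelength (m), > 0.
    """
    if lambda0 <= 0:
        raise ValueError(f"lambda0 must be positive, got {lambda0}")
    if mu_a < 0:
        raise ValueError(f"mu_a must be non-negative, got {mu_a}")
    return mu_a * lambda0 / (4.0 * math.pi)


def imag_index_to_absorption(n_imag: float, lambda0: float) -> float:
    """Inverse of :func:`absorption_to_imag_index`."""
    if lambda0 <= 0:
        raise ValueError(f"lambda0 must be positive, got {lambda0}")
    if n_imag < 0:
        raise ValueError(f"n_imag must be non-negative, got {n_imag}")
    return 4.0 * math.pi * n_imag / lambda0


@dataclass(frozen=True)
class Medium:
    """One material at one vacuum wavelength.

    ``n_imag`` and ``mu_a`` are kept mutually consistent through
    ``mu_a = 4 pi n'' / lambda0``; construct with either one via the
    factory classmethods.
    """

    name: str
    lambda0: float  # vacuum wavelength, m
    n_real: float  # n', dimensionless
    n_imag: float  # n'', dimensionless
    mu_a: float = field(default=None)  # absorption coefficient, m^-1

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.n_real <= 0:
            raise ValueError("n_real must be positive")
        if self.n_imag < 0:
            raise ValueError("n_imag must be non-negative")
        if self.mu_a is None:
            object.__setattr__(
                self, "mu_a", imag_index_to_absorption(self.n_imag, self.lambda0)
            )
        expected = imag_index_to_absorption(self.n_imag, self.lambda0)
        if not math.isclose(self.mu_a, expected, rel_tol=1e-6, abs_tol=1e-30):
            raise ValueError(
                f"mu_a={self.mu_a} inconsistent with n_imag={self.n_imag} "
                f"at lambda0={self.lambda0} (expected {expected})"
            )

    @classmethod
    def from_mu_a(
        cls, name: str, lambda0: float, n_real: float, mu_a: float
    ) -> "Medium":
        return cls(
            name=name,
            lambda0=lambda0,
            n_real=n_real,
            n_imag=absorption_to_imag_index(mu_a, lambda0),
            mu_a=mu_a,
        )

    @property
    def n_complex(self) -> complex:
        """Complex index n = n' - j n''."""
        return complex(self.n_real, -self.n_imag)


@dataclass(frozen=True)
class Permittivity:
    """Relative permittivity eps_r = eps' - j eps'' with eps'' >= 0 stored
    as a magnitude (``eps_imag_mag``)."""

    eps_real: float
    eps_imag_mag: float

    @property
    def eps_complex(self) -> complex:
        return complex(self.eps_real, -self.eps_imag_mag)


def permittivity(medium: Medium) -> Permittivity:
    """Relative permittivity eps_r = n^2 with n = n' - j n''.

    eps' = n'^2 - n''^2 and eps'' = 2 n' n''.
    """
    return Permittivity(
        eps_real=medium.n_real**2 - medium.n_imag**2,
        eps_imag_mag=2.0 * medium.n_real * medium.n_imag,
    )


def permittivity_to_index(perm: Permittivity) -> tuple[float, float]:
    """(n', n'') recovering the index from eps_r = n^2 (principal root)."""
    n = complex(perm.eps_real, -perm.eps_imag_mag) ** 0.5
    if n.real < 0:
        n = -n
    return n.real, -n.imag


def _load_table() -> pd.DataFrame:
    with resources.files("mitodose.data").joinpath("optical_constants.csv").open() as f:
        return pd.read_csv(f, comment="#")


_TABLE: pd.DataFrame | None = None


def _table() -> pd.DataFrame:
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return _TABLE


def medium_lookup(material: str, lambda0: float, table: pd.DataFrame | None = None) -> Medium:
    """Tabulated Medium for ``material`` in {air, saline, glass} at one of
    the supported wavelengths (808, 980, 1064 nm).

    No interpolation: an unlisted wavelength raises ``ValueError``.  An
    alternative constants table (same columns) may be passed to override
    the packaged one.
    """
    tab = table if table is not None else _table()
    lam_nm = lambda0 * 1e9
    rows = tab[
        (tab["material"] == material)
        & (abs(tab["lambda0_nm"] - lam_nm) < 1e-6)
    ]
    if rows.empty:
        if material not in set(tab["material"]):
            raise ValueError(f"unknown material {material!r}")
        raise ValueError(
            f"unsupported wavelength {lam_nm:g} nm for {material!r}; "
            f"tabulated: {sorted(set(tab['lambda0_nm']))} nm (no interpolation)"
        )
    row = rows.iloc[0]
    return Medium.from_mu_a(material, lambda0, float(row["n_real"]), float(row["mu_a_per_m"]))


def mitochondrion_medium(lambda0: float, n_real: float = 1.40, mu_a: float = 85.0) -> Medium:
    """Effective homogeneous mitochondrion medium.

    Defaults are the midpoints of the literature ranges
    n'_m in [1.35, 1.45], mu_a,m in [20, 150] m^-1.
    """
    return Medium.from_mu_a("mitochondrion", lambda0, n_real, mu_a)
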