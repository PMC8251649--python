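"""Exact plane-wave solution of the planar chamber stack.

The incubation chamber, away from its vertical walls, is a planar
multilayer: semi-infinite air above, a saline column of thickness
``tss`` (5 mm), optionally a thin effective "mitochondria layer"
(``tm`` ~ 1 um) resting on the glass, the glass floor of thickness
``tg`` (2 mm), and semi-infinite air below.  A normally incident
monochromatic plane wave (the flat-top laser beam) is solved exactly
with a transfer-matrix recursion, giving the piecewise field

    E(z) = A_l exp(-j k_l (z - z_l)) + B_l exp(+j k_l (z - z_l))
    H(z) = [A_l exp(-j k_l (z - z_l)) - B_l exp(+j k_l (z - z_l))] / eta_l

in every layer l (phasors, e^{+j omega t} convention, z increasing
downward from the air-saline interface at z = 0, k_l = k0 n_l,
eta_l = eta0 / n_l).

This profile serves two purposes: it IS the rough one-dimensional model
of the experiment (with the mitochondria layer included), and it is the
incident field driving the three-dimensional scattering solvers (without
the mitochondria layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as C0, epsilon_0 as EPS0, mu_0 as MU0

from .media import Medium, medium_lookup, permittivity

ETA0 = math.sqrt(MU0 / EPS0)  # free-space wave impedance, ohm

__all__ = [
    "ETA0",
    "PlaneWaveSource",
    "LayerStack",
    "Field1DProfile",
    "build_stack",
    "tmm_solve",
    "layer_dose_1d",
]


@dataclass(frozen=True)
class PlaneWaveSource:
    """Normally incident uniform plane wave defined by its power density.

    The amplitude in the first (air) medium is E0 = sqrt(2 eta0 S);
    1 W/cm^2 gives 2744.9 V/m.  Polarization (x or y) is degenerate in
    1D and recorded for bookkeeping by the 3D solvers.
    """

    power_density: float = 1.0e4  # W/m^2 (1 W/cm^2)
    lambda0: float = 980e-9  # vacuum wavelength, m
    polarization: str = "y"

    def __post_init__(self):
        if self.power_density <= 0:
            raise ValueError("power_density must be positive")
        if self.polarization not in ("x", "y"):
            raise ValueError("polarization must be 'x' or 'y'")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * C0 / self.lambda0

    @property
    def amplitude(self) -> float:
        """Peak electric-field amplitude in air, V/m."""
        return math.sqrt(2.0 * ETA0 * self.power_density)


@dataclass(frozen=True)
class LayerStack:
    """Ordered planar layers; first and last are semi-infinite.

    ``boundaries[i]`` is the z coordinate (m) of the interface between
    layer i and layer i+1; z = 0 at the air-saline interface, increasing
    downward toward the glass.
    """

    layers: tuple[Medium, ...]
    thicknesses: tuple[float, ...]  # same length; inf for first/last
    mito_index: int | None = None  # index of the mitochondria layer, if any

    def __post_init__(self):
        if len(self.layers) != len(self.thicknesses):
            raise ValueError("layers and thicknesses length mismatch")
        if len(self.layers) < 2:
            raise ValueError("need at least two layers")
        for t in self.thicknesses[1:-1]:
            if not (t > 0):
                raise ValueError("interior layer thicknesses must be positive")
        if not math.isinf(self.thicknesses[0]) or not math.isinf(self.thicknesses[-1]):
            raise ValueError("first and last layers must be semi-infinite")

    @property
    def boundaries(self) -> np.ndarray:
        """Interface depths, shape (n_layers - 1,)."""
        interior = np.asarray(self.thicknesses[1:-1], dtype=float)
        return np.concatenate([[0.0], np.cumsum(interior)])

    def layer_of(self, z: float) -> int:
        b = self.boundaries
        return int(np.searchsorted(b, z, side="right"))


def build_stack(
    lambda0: float,
    include_mito_layer: bool = False,
    tm: float = 1e-6,
    mito_medium: Medium | None = None,
    tss: float = 5e-3,
    tg: float = 2e-3,
) -> LayerStack:
    """Chamber stack air / saline(tss) / [mito(tm)] / glass(tg) / air.

    The effective mitochondria layer, when included, rests on the glass:
    its bottom face coincides with the saline-glass interface, so with the
    defaults it spans z in (tss - tm, tss) = (4.999, 5) mm for tm = 1 um.
    """
    if tss <= 0 or tg <= 0:
        raise ValueError("tss and tg must be positive")
    air = medium_lookup("air", lambda0)
    ss = medium_lookup("saline", lambda0)
    gl = medium_lookup("glass", lambda0)
    inf = math.inf
    if not include_mito_layer:
        return LayerStack((air, ss, gl, air), (inf, tss, tg, inf))
    if not (tm > 0):
        raise ValueError("tm must be positive when the mito layer is included")
    if tm >= tss:
        raise ValueError("tm must be smaller than tss")
    if mito_medium is None:
        from .media import mitochondrion_medium

        mito_medium = mitochondrion_medium(lambda0)
    return LayerStack(
        (air, ss, mito_medium, gl, air),
        (inf, tss - tm, tm, tg, inf),
        mito_index=2,
    )


@dataclass
class Field1DProfile:
    """Piecewise plane-wave phasor solution of a :class:`LayerStack`."""

    stack: LayerStack
    source: PlaneWaveSource
    A: np.ndarray  # forward amplitudes per layer (referenced at layer top), V/m
    B: np.ndarray  # backward amplitudes per layer, V/m
    k: np.ndarray  # complex wavenumbers per layer, 1/m
    eta: np.ndarray  # complex wave impedances per layer, ohm
    iface_E: np.ndarray  # tangential E at each interface, V/m
    iface_H: np.ndarray  # tangential H at each interface, A/m
    r: complex = field(init=False)
    t: complex = field(init=False)

    def __post_init__(self):
        self.r = complex(self.B[0] / self.A[0])
        self.t = complex(self.A[-1] / self.A[0])

    def field_at(self, z) -> tuple[np.ndarray, np.ndarray]:
        """(E, H) phasors at depth(s) z; tangential scalar components.

        Total fields are propagated from the nearest interface with the
        transmission-line relations

            E(zi + d) = E_i cos(k d) - j eta H_i sin(k d)
            H(zi + d) = H_i cos(k d) - j (E_i / eta) sin(k d),

        so interface continuity is exact by construction even though the
        millimetric layers span tens of thousands of radians of phase.
        Vectorized over z.
        """
        z = np.atleast_1d(np.asarray(z, dtype=float))
        b = self.stack.boundaries
        lay = np.searchsorted(b, z, side="right")
        E = np.empty(z.shape, dtype=complex)
        H = np.empty(z.shape, dtype=complex)
        L = len(self.stack.layers)
        for l in np.unique(lay):
            m = lay == l
            k, eta = self.k[l], self.eta[l]
            if l == L - 1:
                # transmitted region: pure forward wave from the last interface
                ph = np.exp(-1j * k * (z[m] - b[-1]))
                E[m] = self.iface_E[-1] * ph
                H[m] = self.iface_H[-1] * ph
                continue
            # nearest interface: top (l-1) or bottom (l) of the layer
            if l == 0:
                iref = np.zeros(np.count_nonzero(m), dtype=int)
            else:
                mid = 0.5 * (b[l - 1] + b[l])
                iref = np.where(z[m] <= mid, l - 1, l)
            d = z[m] - b[iref]
            Ei, Hi = self.iface_E[iref], self.iface_H[iref]
            ckd, skd = np.cos(k * d), np.sin(k * d)
            E[m] = Ei * ckd - 1j * eta * Hi * skd
            H[m] = Hi * ckd - 1j * (Ei / eta) * skd
        if E.size == 1:
            return E[0], H[0]
        return E, H


def tmm_solve(stack: LayerStack, source: PlaneWaveSource) -> Field1DProfile:
    """Exact transfer-matrix solution of the stack under the source.

    Backward-substitution form: the transmitted wave in the last layer is
    normalized to unit amplitude, tangential E and H are propagated upward
    through every interface, and the whole solution is rescaled so the
    forward amplitude in the first layer equals the source amplitude.
    """
    k0 = 2.0 * math.pi / source.lambda0
    n = np.array([m.n_complex for m in stack.layers])
    for m in stack.layers:
        if abs(m.lambda0 - source.lambda0) > 1e-15:
            raise ValueError("stack media resolved at a different wavelength")
    k = k0 * n
    eta = ETA0 / n
    L = len(stack.layers)
    A = np.zeros(L, dtype=complex)
    B = np.zeros(L, dtype=complex)
    iface_E = np.zeros(L - 1, dtype=complex)
    iface_H = np.zeros(L - 1, dtype=complex)
    A[-1] = 1.0
    # Tangential E, H just above the bottom of layer l (= top of layer l+1).
    E_if = A[-1]
    H_if = A[-1] / eta[-1]
    iface_E[-1], iface_H[-1] = E_if, H_if
    for l in range(L - 2, -1, -1):
        # Amplitudes in layer l referenced to its top boundary; the
        # interface with layer l+1 is a thickness t_l below it (t=0 for
        # the semi-infinite first layer, whose reference is z=0).
        t_l = stack.thicknesses[l] if l > 0 else 0.0
        phase = np.exp(-1j * k[l] * t_l)
        A[l] = 0.5 * (E_if + eta[l] * H_if) / phase
        B[l] = 0.5 * (E_if - eta[l] * H_if) * phase
        E_if = A[l] + B[l]
        H_if = (A[l] - B[l]) / eta[l]
        if l > 0:
            iface_E[l - 1], iface_H[l - 1] = E_if, H_if
        # E_if, H_if now refer to the top boundary of layer l, i.e. the
        # interface with layer l-1.
    scale = source.amplitude / A[0]
    A *= scale
    B *= scale
    iface_E *= scale
    iface_H *= scale
    return Field1DProfile(stack=stack, source=source, A=A, B=B, k=k, eta=eta,
                          iface_E=iface_E, iface_H=iface_H)


def _expm1_ratio(c: complex, t: float) -> complex:
    """(exp(c t) - 1) / c, with the c -> 0 limit t."""
    ct = complex(c) * t
    if abs(ct) < 1e-8:
        return t * (1 + 0.5 * ct + ct * ct / 6.0)
    return (np.exp(ct) - 1.0) / complex(c)


def _layer_mean_squares(A: complex, B: complex, k: complex, t: float):
    """Exact thickness-averages of |A e^{-jkz} + B e^{jkz}|^2 and of the
    corresponding difference term (for H), over z in (0, t)."""
    a = -k.imag  # decay rate, >= 0 for passive media
    b = k.real
    fa_minus = _expm1_ratio(-2.0 * a, t)  # int e^{-2az}
    fa_plus = _expm1_ratio(2.0 * a, t)  # int e^{+2az}
    g = _expm1_ratio(-2j * b, t)  # int e^{-2jbz}
    cross = 2.0 * (A * np.conj(B) * g).real
    common = (abs(A) ** 2 * fa_minus + abs(B) ** 2 * fa_plus).real
    return (common + cross) / t, (common - cross) / t


def layer_dose_1d(
    profile: Field1DProfile,
    layer_index: int | None = None,
    medium: Medium | None = None,
    n_quad: int | None = None,
) -> tuple[float, float]:
    """Average energy density Ed (J/m^3) and dissipated power density Pd
    (W/m^3) over the mitochondria layer of a 1D profile.

    Ed = (1/t) Int (1/4) (eps0 eps' |E|^2 + mu0 |H|^2) dz
    Pd = (1/t) Int (1/2) omega eps0 eps'' |E|^2 dz

    The piecewise-exponential integrals are evaluated in closed form by
    default; passing ``n_quad`` switches to Gauss-Legendre quadrature
    (useful as an independent cross-check for thin layers).
    """
    if layer_index is None:
        layer_index = profile.stack.mito_index
    if layer_index is None:
        raise ValueError("stack has no mitochondria layer; pass layer_index")
    if not (0 < layer_index < len(profile.stack.layers) - 1):
        raise ValueError("layer_index must be an interior layer")
    if medium is None:
        medium = profile.stack.layers[layer_index]
    b = profile.stack.boundaries
    z_top, z_bot = b[layer_index - 1], b[layer_index]
    thickness = z_bot - z_top
    perm = permittivity(medium)
    omega = profile.source.omega
    if n_quad is None:
        l = layer_index
        e2, h2eta = _layer_mean_squares(
            profile.A[l], profile.B[l], profile.k[l], thickness
        )
        h2 = h2eta / abs(profile.eta[l]) ** 2
        Ed = 0.25 * (EPS0 * perm.eps_real * e2 + MU0 * h2)
        Pd = 0.5 * omega * EPS0 * perm.eps_imag_mag * e2
        return float(Ed), float(Pd)
    x, w = np.polynomial.legendre.leggauss(n_quad)
    z = 0.5 * (z_top + z_bot) + 0.5 * thickness * x
    w = 0.5 * thickness * w
    E, H = profile.field_at(z)
    e2 = np.abs(E) ** 2
    h2 = np.abs(H) ** 2
    Ed = np.sum(w * 0.25 * (EPS0 * perm.eps_real * e2 + MU0 * h2)) / thickness
    Pd = np.sum(w * 0.5 * omega * EPS0 * perm.eps_imag_mag * e2) / thickness
    return float(Ed), float(Pd)


def poynting_z(profile: Field1DProfile, z) -> float | np.ndarray:
    """Time-averaged z-directed Poynting flux (W/m^2) at depth z:
    S_z = (1/2) Re(E H*)."""
    E, H = profile.field_at(z)
    return 0.5 * np.real(E * np.conj(H))
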