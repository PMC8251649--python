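"""Independent oracles used by the test suite.

These are written against the same physics but by entirely different
routes than the package code: a transmission-line (total-field ABCD)
recursion for the planar stack, and a Mie series for the sphere.  They
share no code with ``mitodose``.
"""

from __future__ import annotations

import cmath
import math

import numpy as np

ETA0 = 376.73031366857


# ---------------------------------------------------------------------------
# impedance-recursion / ABCD oracle for planar stacks

def abcd_stack_fields(n_list, t_list, lambda0, E0, z_samples):
    """Total tangential (E, H) at depths ``z_samples`` for a stack of
    complex indices ``n_list`` (first/last semi-infinite, thicknesses
    ``t_list`` for the interior layers), e^{+j omega t} convention.

    Transmission-line formulation: within a layer of wavenumber k and
    impedance eta, the total fields a distance d above a reference point
    obey

        E(z-d) = E(z) cos(k d) + j eta H(z) sin(k d)
        H(z-d) = j E(z) sin(k d) / eta + H(z) cos(k d).

    The load is the matched last medium (H = E/eta_last); the recursion
    walks up to the first interface, the air-side amplitudes are read off
    and everything is scaled to an incident amplitude E0.
    """
    k0 = 2 * math.pi / lambda0
    n_list = [complex(n) for n in n_list]
    etas = [ETA0 / n for n in n_list]
    ks = [k0 * n for n in n_list]
    boundaries = np.concatenate([[0.0], np.cumsum(t_list)])

    # fields at the bottom interface (top of the last medium), load side
    E_b, H_b = 1.0 + 0j, (1.0 + 0j) / etas[-1]
    interface_EH = {len(t_list): (E_b, H_b)}
    for li in range(len(t_list) - 1, -1, -1):
        k, eta, d = ks[li + 1], etas[li + 1], t_list[li]
        ckd, skd = cmath.cos(k * d), cmath.sin(k * d)
        E_t = E_b * ckd + 1j * eta * H_b * skd
        H_t = 1j * E_b * skd / eta + H_b * ckd
        interface_EH[li] = (E_t, H_t)
        E_b, H_b = E_t, H_t
    # air side: E = Ei(1+r), H = Ei(1-r)/eta0 at z=0
    E_top, H_top = interface_EH[0]
    Ei = 0.5 * (E_top + etas[0] * H_top)
    scale = E0 / Ei
    r = (E_top - etas[0] * H_top) / (E_top + etas[0] * H_top)

    E_out = np.empty(len(z_samples), dtype=complex)
    H_out = np.empty(len(z_samples), dtype=complex)
    for m, z in enumerate(z_samples):
        li = int(np.searchsorted(boundaries, z, side="right"))  # layer index
        if li == 0:
            # air above: incident + reflected
            E_out[m] = scale * Ei * (
                cmath.exp(-1j * ks[0] * z) + r * cmath.exp(1j * ks[0] * z)
            )
            H_out[m] = scale * Ei * (
                cmath.exp(-1j * ks[0] * z) - r * cmath.exp(1j * ks[0] * z)
            ) / etas[0]
        elif li == len(n_list) - 1:
            zb = boundaries[-1]
            E_b, H_b = interface_EH[len(t_list)]
            ph = cmath.exp(-1j * ks[-1] * (z - zb))
            E_out[m] = scale * E_b * ph
            H_out[m] = scale * H_b * ph
        else:
            # propagate down from the layer's top interface
            zt = boundaries[li - 1]
            E_t, H_t = interface_EH[li - 1]
            k, eta = ks[li], etas[li]
            d = -(z - zt)  # moving downward: reuse the up-propagation with -d
            ckd, skd = cmath.cos(k * d), cmath.sin(k * d)
            E_out[m] = scale * (E_t * ckd + 1j * eta * H_t * skd)
            H_out[m] = scale * (1j * E_t * skd / eta + H_t * ckd)
    return E_out, H_out, complex(r)


# ---------------------------------------------------------------------------
# Mie series (Bohren & Huffman style, e^{-i omega t}; callers convert)

def mie_efficiencies(m: complex, x: float) -> tuple[float, float, float]:
    """(Qext, Qsca, Qabs) for a homogeneous sphere.

    ``m`` is the relative complex index in the e^{-i omega t} convention
    (positive imaginary part = absorption) and ``x = 2 pi n_host R /
    lambda0`` the size parameter.
    """
    nmax = int(x + 4 * x ** (1 / 3) + 10)
    nmx = nmax + 15
    D = np.zeros(nmx + 1, dtype=complex)
    mx = m * x
    for n in range(nmx, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    psi_nm2, psi_nm1 = math.cos(x), math.sin(x)
    chi_nm2, chi_nm1 = -math.sin(x), math.cos(x)
    qext = qsca = 0.0
    for n in range(1, nmax + 1):
        psi = (2 * n - 1) / x * psi_nm1 - psi_nm2
        chi = (2 * n - 1) / x * chi_nm1 - chi_nm2
        xi = complex(psi, -chi)
        xi_nm1 = complex(psi_nm1, -chi_nm1)
        an = ((D[n] / m + n / x) * psi - psi_nm1) / ((D[n] / m + n / x) * xi - xi_nm1)
        bn = ((D[n] * m + n / x) * psi - psi_nm1) / ((D[n] * m + n / x) * xi - xi_nm1)
        qext += (2 * n + 1) * (an.real + bn.real)
        qsca += (2 * n + 1) * (abs(an) ** 2 + abs(bn) ** 2)
        psi_nm2, chi_nm2 = psi_nm1, chi_nm1
        psi_nm1, chi_nm1 = psi, chi
    qext *= 2 / x**2
    qsca *= 2 / x**2
    return qext, qsca, qext - qsca
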