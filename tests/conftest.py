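import pytest

from mitodose.media import Medium, mitochondrion_medium
from mitodose.multilayer import PlaneWaveSource, build_stack, tmm_solve
from mitodose.scenes import Ellipsoid, Scene, voxelize
from mitodose.solver import cdm_solve, uniform_plane_wave

LAM = 980e-9


@pytest.fixture(scope="session")
def source980():
    return PlaneWaveSource(power_density=1e4, lambda0=LAM, polarization="y")


@pytest.fixture(scope="session")
def profile980(source980):
    """Incident (no-mito) chamber field at 980 nm."""
    return tmm_solve(build_stack(LAM), source980)


@pytest.fixture(scope="session")
def profile980_mito(source980):
    """1D model with the 1 um effective mitochondria layer at 980 nm."""
    med = mitochondrion_medium(LAM)
    return tmm_solve(build_stack(LAM, include_mito_layer=True, tm=1e-6,
                                 mito_medium=med), source980)


def sphere_grid(radius, n_real, mu_a, spacing, n_bg=1.328, lam=LAM):
    """Voxelized sphere in a lossless saline-like background (for Mie
    comparisons)."""
    bg = Medium("bg", lam, n_bg, 0.0)
    mat = Medium.from_mu_a("sphere", lam, n_real, mu_a)
    # spheroid with a vanishing eccentricity stands in for the sphere
    e = Ellipsoid((0.0, 0.0, 0.0), 2 * radius * (1 + 1e-9), 2 * radius,
                  (1.0, 0.0, 0.0), mat)
    scene = Scene([e], bg, floor_z=1.0, label="sphere", central_indices=(0,))
    return voxelize(scene, spacing)


@pytest.fixture(scope="session")
def mie_sphere_solution():
    """CDM solution for the reference sphere (r=0.5 um, n=1.40-j6.63e-6)
    in lossless saline under a uniform plane wave."""
    grid = sphere_grid(0.5e-6, 1.40, 85.0, LAM / (20 * 1.40))
    E0 = 2744.9
    Ei, Hi = uniform_plane_wave(grid.positions, LAM, 1.328 + 0j, E0, "y")
    return cdm_solve(grid, Ei, Hi), E0


@pytest.fixture(scope="session")
def isolated980():
    """Isolated mitochondrion at 980 nm, default parameters and spacing."""
    from mitodose.reporting import solve_preset

    return solve_preset("isolated", LAM)


@pytest.fixture(scope="session")
def sweep980():
    """Full 980 nm dose sweep (dm x n'_m x polarization x configuration)
    at mu_a,m = 85 m^-1, scaled-down spacings."""
    from mitodose.reporting import discussion_sweep

    return discussion_sweep(980e-9)


@pytest.fixture(scope="session")
def sweep_all(sweep980):
    """The same sweep pooled over all three wavelengths."""
    import pandas as pd

    from mitodose.reporting import discussion_sweep

    frames = [sweep980]
    for lam in (808e-9, 1064e-9):
        frames.append(discussion_sweep(lam))
    return pd.concat(frames, ignore_index=True)
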