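import math

import numpy as np
import pytest

from mitodose.media import mitochondrion_medium
from mitodose.scenes import (
    FLOOR_Z,
    Ellipsoid,
    GeometryError,
    Scene,
    build_model,
    random_scene,
    voxelize,
)

LAM = 980e-9
UM = 1e-6


class TestEllipsoid:
    def test_validation(self):
        med = mitochondrion_medium(LAM)
        with pytest.raises(ValueError):
            Ellipsoid((0, 0, 0), 3 * UM, 3 * UM, (1, 0, 0), med)  # not prolate
        with pytest.raises(ValueError):
            Ellipsoid((0, 0, 0), 3 * UM, 1 * UM, (2, 0, 0), med)  # not unit

    def test_volume(self):
        med = mitochondrion_medium(LAM)
        e = Ellipsoid((0, 0, 0), 3 * UM, 1 * UM, (1, 0, 0), med)
        assert e.volume == pytest.approx(4 / 3 * math.pi * 1.5 * 0.5 * 0.5 * UM**3)


class TestBuilders:
    def test_isolated_occupies_last_micron(self):
        sc = build_model("isolated", LAM, dm=1 * UM)
        (e,) = sc.ellipsoids
        lo, hi = e.center[2] - e.b, e.center[2] + e.b
        assert hi == pytest.approx(5e-3, rel=1e-12)
        assert lo == pytest.approx(4.999e-3, rel=1e-12)

    def test_three_layer_counts(self):
        sc = build_model("three_layer_21", LAM)
        assert len(sc.ellipsoids) == 21
        z_centers = sorted({round(e.center[2], 12) for e in sc.ellipsoids})
        assert len(z_centers) == 3
        assert len(sc.central_indices) == 3

    def test_rot90_variant_rotates_middle_layer(self):
        sc = build_model("three_layer_21_rot90", LAM)
        by_z = {}
        for e in sc.ellipsoids:
            by_z.setdefault(round(e.center[2], 12), []).append(e)
        zs = sorted(by_z)
        mid = by_z[zs[1]]
        assert all(abs(e.axis_dir[1]) > 0.99 for e in mid)
        for z in (zs[0], zs[2]):
            assert all(abs(e.axis_dir[0]) > 0.99 for e in by_z[z])

    def test_seven_vertical_span(self):
        sc = build_model("seven_vertical", LAM)
        assert len(sc.ellipsoids) == 7
        for e in sc.ellipsoids:
            assert abs(e.axis_dir[2]) == 1.0
            assert e.center[2] + e.a == pytest.approx(5e-3, rel=1e-12)
            assert e.center[2] - e.a == pytest.approx(4.997e-3, rel=1e-12)

    def test_periodic_needs_odd_shape(self):
        with pytest.raises(ValueError, match="odd"):
            build_model("periodic_array", LAM, array_shape=(4, 4))

    def test_huge_gap_still_seven(self):
        sc = build_model("seven_horizontal", LAM, gap=2 * UM)
        assert len(sc.ellipsoids) == 7
        sc.validate()  # non-overlap invariant holds at any gap

    @pytest.mark.parametrize("dm", [0.5 * UM, 0.75 * UM, 1.0 * UM])
    @pytest.mark.parametrize(
        "kind",
        ["isolated", "seven_horizontal", "seven_vertical", "three_layer_21",
         "three_layer_21_rot90"],
    )
    def test_invariants_across_dm_grid(self, kind, dm):
        sc = build_model(kind, LAM, dm=dm)
        sc.validate()
        for e in sc.ellipsoids:
            lo = e.center[2] - e.half_height()
            assert lo >= FLOOR_Z - 3.5 * UM - 1e-12  # pile height bound

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("dodecahedron")

    def test_overlap_detected(self):
        med = mitochondrion_medium(LAM)
        zc = FLOOR_Z - 0.5 * UM
        e1 = Ellipsoid((0, 0, zc), 3 * UM, 1 * UM, (1, 0, 0), med)
        e2 = Ellipsoid((0, 0.5 * UM, zc), 3 * UM, 1 * UM, (1, 0, 0), med)
        sc = Scene([e1, e2], build_model("isolated", LAM).background)
        with pytest.raises(GeometryError, match="overlap"):
            sc.validate()


class TestRandomScenes:
    def test_deterministic_per_seed(self):
        a = random_scene(12, seed=7)
        b = random_scene(12, seed=7)
        assert [e.center for e in a.ellipsoids] == [e.center for e in b.ellipsoids]
        assert [e.axis_dir for e in a.ellipsoids] == [e.axis_dir for e in b.ellipsoids]
        c = random_scene(12, seed=8)
        assert [e.center for e in a.ellipsoids] != [e.center for e in c.ellipsoids]

    def test_single_body_congruent_to_isolated(self):
        sc = random_scene(1, seed=3)
        (e,) = sc.ellipsoids
        iso = build_model("isolated", LAM).ellipsoids[0]
        assert e.lm == iso.lm and e.dm == iso.dm
        assert e.center[2] == pytest.approx(iso.center[2])
        assert e.axis_dir[2] == 0.0

    def test_fifty_bodies_pairwise_separated(self):
        """Brute-force boundary-sampling check of all pairs."""
        sc = random_scene(50, seed=11, region_radius=20 * UM)
        th = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        boundaries = []
        for e in sc.ellipsoids:
            u = np.array(e.axis_dir)
            v = np.array([-u[1], u[0], 0.0])
            ring = (
                np.asarray(e.center)[None, :]
                + np.outer(np.cos(th), e.a * u)
                + np.outer(np.sin(th), e.b * v)
            )
            boundaries.append(ring[:, :2])
        for i in range(len(boundaries)):
            for k in range(i + 1, len(boundaries)):
                # mid-plane rings must not interpenetrate: every boundary
                # point of one body lies outside the other
                d = sc.ellipsoids[k]
                pts = np.c_[boundaries[i], np.full(len(th), d.center[2])]
                assert not d.contains(pts).any()

    def test_packing_failure(self):
        with pytest.raises(GeometryError, match="could not place"):
            random_scene(200, seed=0, region_radius=5 * UM, max_tries=300)


class TestVoxelize:
    def test_volume_within_2pct_at_default_spacing(self):
        sc = build_model("isolated", LAM, dm=1 * UM)
        grid = voxelize(sc, 40e-9)
        analytic = 4 / 3 * math.pi * 1.5 * 0.5 * 0.5 * UM**3  # 1.5708 um^3
        assert grid.owner_volume(0) == pytest.approx(analytic, rel=0.02)

    def test_volume_converges_with_spacing(self):
        sc = build_model("isolated", LAM, dm=1 * UM)
        errs = []
        for d in (100e-9, 50e-9, 25e-9):
            v = voxelize(sc, d).owner_volume(0)
            errs.append(abs(v / sc.ellipsoids[0].volume - 1))
        assert errs[2] < errs[0]
        assert errs[2] < 5e-3

    def test_resolution_error(self):
        sc = build_model("isolated", LAM, dm=0.5 * UM)
        with pytest.raises(ValueError, match="coarser"):
            voxelize(sc, 0.2 * UM)

    def test_empty_scene(self):
        sc = Scene([], build_model("isolated", LAM).background)
        grid = voxelize(sc, 50e-9)
        assert grid.n_dipoles == 0

    def test_owner_tagging(self):
        sc = build_model("seven_horizontal", LAM)
        grid = voxelize(sc, 100e-9)
        assert set(np.unique(grid.owner)) == set(range(7))
        # every occupied voxel center really is inside its ellipsoid
        pos = grid.positions
        for i, e in enumerate(sc.ellipsoids):
            sel = grid.owner == i
            assert e.contains(pos[sel]).all()


class TestSceneYaml:
    def test_roundtrip(self):
        sc = build_model("seven_horizontal", LAM, dm=0.75 * UM)
        sc2 = Scene.from_yaml(sc.to_yaml())
        assert sc2.label == sc.label
        assert len(sc2.ellipsoids) == 7
        for a, b in zip(sc.ellipsoids, sc2.ellipsoids):
            assert np.allclose(a.center, b.center)
            assert a.medium.n_complex == pytest.approx(b.medium.n_complex)
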