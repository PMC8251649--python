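"""Geometry of the mitochondrion configurations and their voxelization.

Mitochondria are modeled as homogeneous prolate spheroids of length
``lm`` = 3 um (long semi-axis 1.5 um) and diameter ``dm`` in
{0.5, 0.75, 1} um, resting at the bottom of the saline column
(floor at z = tss = 5 mm; z increases downward, so bodies occupy
z in (floor - height, floor)).

Deterministic builders produce the fixed study configurations:

* ``isolated``            - one horizontal spheroid on the chamber axis;
* ``seven_horizontal``    - a central body with 2 coaxial end-to-end and
                            4 side-by-side neighbors, one layer;
* ``seven_vertical``      - 7 standing (long axis vertical) bodies,
                            hexagonal in plan;
* ``three_layer_21``      - three stacked copies of the 7-pattern
                            (middle layer optionally rotated 90 deg);
* ``periodic_array``      - a finite Nx x Ny tiling of the one-body cell,
                            standing in for a periodic arrangement.

A seeded random generator places n non-overlapping horizontal bodies with
uniform in-plane positions and azimuths, emulating the random dispositions
seen in real preparations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.affinity import rotate as shp_rotate, translate as shp_translate
from shapely.geometry import Polygon

from .media import Medium, medium_lookup, mitochondrion_medium

__all__ = [
    "Ellipsoid",
    "Scene",
    "DipoleGrid",
    "build_model",
    "random_scene",
    "voxelize",
    "MODEL_KINDS",
]

FLOOR_Z = 5e-3  # saline-glass interface depth, m
FLOOR_DIAMETER = 1.13e-2  # chamber floor diameter (area ~1 cm^2), m
MAX_CLUSTER_HEIGHT = 3.5e-6  # mitochondria pile no higher than a few um
DEFAULT_GAP = 0.05e-6  # default surface-to-surface gap in builders, m
DEFAULT_LM = 3e-6
DEFAULT_DM = 1e-6

MODEL_KINDS = (
    "isolated",
    "seven_horizontal",
    "seven_vertical",
    "three_layer_21",
    "three_layer_21_rot90",
    "periodic_array",
)


class GeometryError(ValueError):
    """Raised for overlapping or out-of-bounds placements."""


@dataclass(frozen=True)
class Ellipsoid:
    """A prolate spheroid: long semi-axis a = lm/2 along ``axis_dir``,
    transverse semi-axes dm/2."""

    center: tuple[float, float, float]
    lm: float
    dm: float
    axis_dir: tuple[float, float, float]
    medium: Medium

    def __post_init__(self):
        if self.lm <= 0 or self.dm <= 0:
            raise ValueError("lm and dm must be positive")
        if self.dm >= self.lm:
            raise ValueError("transverse diameter must be smaller than length")
        u = np.asarray(self.axis_dir, dtype=float)
        nrm = np.linalg.norm(u)
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ValueError("axis_dir must be a unit vector")

    @property
    def a(self) -> float:
        return self.lm / 2.0

    @property
    def b(self) -> float:
        return self.dm / 2.0

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.a * self.b * self.b

    @property
    def is_vertical(self) -> bool:
        return abs(self.axis_dir[2]) > 0.99

    def half_height(self) -> float:
        """Vertical half-extent."""
        uz = self.axis_dir[2]
        return math.sqrt((self.a * uz) ** 2 + self.b**2 * (1 - uz**2))

    def half_extents(self) -> np.ndarray:
        """Axis-aligned bounding half-extents along x, y, z."""
        u = np.asarray(self.axis_dir)
        return np.sqrt((self.a * u) ** 2 + self.b**2 * (1 - u**2))

    def contains(self, points: np.ndarray, open_set: bool = True) -> np.ndarray:
        """Boolean mask of points (N, 3) strictly inside (or on, if
        ``open_set`` is False) the spheroid."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        u = np.asarray(self.axis_dir)
        t = p @ u
        r2 = np.einsum("ij,ij->i", p, p) - t**2
        q = (t / self.a) ** 2 + r2 / self.b**2
        return q < 1.0 if open_set else q <= 1.0

    def plan_polygon(self, n_seg: int = 96) -> Polygon:
        """Conservative (circumscribed) polygon of the mid-plane cross
        section projected on the xy plane; used for overlap checks."""
        if self.is_vertical:
            sx = sy = self.b
            ang = 0.0
        else:
            sx, sy = self.a, self.b
            ang = math.degrees(math.atan2(self.axis_dir[1], self.axis_dir[0]))
        # circumscribed regular polygon of the unit circle
        scale = 1.0 / math.cos(math.pi / n_seg)
        th = np.linspace(0, 2 * math.pi, n_seg, endpoint=False)
        pts = np.c_[sx * scale * np.cos(th), sy * scale * np.sin(th)]
        poly = Polygon(pts)
        poly = shp_rotate(poly, ang, origin=(0, 0))
        return shp_translate(poly, self.center[0], self.center[1])


def _z_interval(e: Ellipsoid) -> tuple[float, float]:
    h = e.half_height()
    return e.center[2] - h, e.center[2] + h


def _pair_overlaps(e1: Ellipsoid, e2: Ellipsoid) -> bool:
    """True if the two spheroids intersect with positive volume.

    Cheap separations first (bounding spheres, disjoint z-slabs); bodies
    sharing a mid-plane height are reduced to their plan-view ellipse
    cross sections (valid for convex bodies symmetric about the same
    horizontal plane).  The ellipse test uses circumscribed polygons, so
    it errs on the side of reporting overlap.
    """
    c1, c2 = np.asarray(e1.center), np.asarray(e2.center)
    d = np.linalg.norm(c1 - c2)
    if d >= e1.a + e2.a:
        return False
    z1, z2 = _z_interval(e1), _z_interval(e2)
    tol = 1e-12  # touching bodies are not overlapping
    if z1[1] <= z2[0] + tol or z2[1] <= z1[0] + tol:
        return False
    if abs(e1.center[2] - e2.center[2]) < 1e-12:
        return e1.plan_polygon().intersects(e2.plan_polygon())
    # Conservative fallback for unequal heights with overlapping z-slabs:
    # compare plan footprints (projection can only enlarge the bodies).
    return e1.plan_polygon().intersects(e2.plan_polygon())


@dataclass
class Scene:
    """A set of non-overlapping mitochondria near the chamber floor."""

    ellipsoids: list[Ellipsoid]
    background: Medium
    floor_z: float = FLOOR_Z
    label: str = "scene"
    central_indices: tuple[int, ...] = (0,)  # dose-target bodies

    def validate(self) -> None:
        r_floor = FLOOR_DIAMETER / 2.0
        for i, e in enumerate(self.ellipsoids):
            lo, hi = _z_interval(e)
            if hi > self.floor_z + 1e-12:
                raise GeometryError(f"ellipsoid {i} extends below the floor")
            if lo < self.floor_z - MAX_CLUSTER_HEIGHT - 1e-12:
                raise GeometryError(f"ellipsoid {i} higher than {MAX_CLUSTER_HEIGHT*1e6} um above the floor")
            if math.hypot(e.center[0], e.center[1]) + e.a > r_floor:
                raise GeometryError(f"ellipsoid {i} outside the chamber floor disc")
        n = len(self.ellipsoids)
        for i in range(n):
            for k in range(i + 1, n):
                if _pair_overlaps(self.ellipsoids[i], self.ellipsoids[k]):
                    raise GeometryError(f"ellipsoids {i} and {k} overlap")

    @property
    def lambda0(self) -> float:
        return self.background.lambda0

    def to_yaml(self) -> str:
        """Human-readable scene description (centers, axes, media)."""
        import yaml

        def med(m: Medium) -> dict:
            return {"name": m.name, "lambda0_nm": m.lambda0 * 1e9,
                    "n_real": m.n_real, "mu_a_per_m": m.mu_a}

        doc = {
            "label": self.label,
            "floor_z_mm": self.floor_z * 1e3,
            "background": med(self.background),
            "central_indices": list(self.central_indices),
            "ellipsoids": [
                {
                    "center_um": [c * 1e6 for c in e.center],
                    "lm_um": e.lm * 1e6,
                    "dm_um": e.dm * 1e6,
                    "axis_dir": list(e.axis_dir),
                    "medium": med(e.medium),
                }
                for e in self.ellipsoids
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Scene":
        import yaml

        doc = yaml.safe_load(text)

        def med(d: dict) -> Medium:
            return Medium.from_mu_a(d["name"], d["lambda0_nm"] * 1e-9,
                                    d["n_real"], d["mu_a_per_m"])

        ells = [
            Ellipsoid(
                tuple(c * 1e-6 for c in d["center_um"]),
                d["lm_um"] * 1e-6,
                d["dm_um"] * 1e-6,
                tuple(d["axis_dir"]),
                med(d["medium"]),
            )
            for d in doc["ellipsoids"]
        ]
        scene = cls(ells, med(doc["background"]),
                    floor_z=doc["floor_z_mm"] * 1e-3, label=doc["label"],
                    central_indices=tuple(doc["central_indices"]))
        scene.validate()
        return scene


def _horizontal(cx, cy, cz, azimuth_deg, lm, dm, medium) -> Ellipsoid:
    th = math.radians(azimuth_deg)
    return Ellipsoid((cx, cy, cz), lm, dm, (math.cos(th), math.sin(th), 0.0), medium)


def _seven_layer_centers(lm: float, dm: float, gap: float) -> list[tuple[float, float]]:
    """(x, y) offsets of the 7-in-a-layer pattern: central body, two
    coaxial end-to-end neighbors (+-(lm+gap) in x) and four side-by-side
    neighbors (+-(dm+gap) in y at x = +-(lm+gap)/2... ) -- lateral pairs
    flank the center, axial pair continues the line."""
    px = lm + gap
    py = dm + gap
    return [
        (0.0, 0.0),
        (px, 0.0),
        (-px, 0.0),
        (px / 2.0, py),
        (-px / 2.0, py),
        (px / 2.0, -py),
        (-px / 2.0, -py),
    ]


def build_model(
    kind: str,
    lambda0: float = 980e-9,
    dm: float = DEFAULT_DM,
    lm: float = DEFAULT_LM,
    gap: float = DEFAULT_GAP,
    mito_medium: Medium | None = None,
    rot90_middle: bool | None = None,
    array_shape: tuple[int, int] = (9, 9),
    floor_z: float = FLOOR_Z,
) -> Scene:
    """Build one of the named study configurations (see module docstring).

    ``central_indices`` of the returned scene designate the dose-target
    bodies: the central mitochondrion, or the three per-layer centrals of
    the 21-body models.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    if not (0.4e-6 <= dm <= 1.2e-6):
        raise ValueError("dm outside the supported range [0.4, 1.2] um")
    if gap < 0:
        raise GeometryError("gap must be non-negative")
    if mito_medium is None:
        mito_medium = mitochondrion_medium(lambda0)
    bg = medium_lookup("saline", lambda0)
    zc = floor_z - dm / 2.0  # horizontal body resting on the floor
    ells: list[Ellipsoid] = []
    centrals: tuple[int, ...] = (0,)

    if kind == "isolated":
        ells = [_horizontal(0, 0, zc, 0, lm, dm, mito_medium)]
    elif kind == "seven_horizontal":
        for x, y in _seven_layer_centers(lm, dm, gap):
            ells.append(_horizontal(x, y, zc, 0, lm, dm, mito_medium))
    elif kind == "seven_vertical":
        zv = floor_z - lm / 2.0  # standing on the floor
        pitch = dm + gap
        ells.append(Ellipsoid((0, 0, zv), lm, dm, (0, 0, 1.0), mito_medium))
        for k in range(6):
            th = math.pi / 3.0 * k
            ells.append(
                Ellipsoid(
                    (pitch * math.cos(th), pitch * math.sin(th), zv),
                    lm,
                    dm,
                    (0, 0, 1.0),
                    mito_medium,
                )
            )
    elif kind in ("three_layer_21", "three_layer_21_rot90"):
        if rot90_middle is None:
            rot90_middle = kind.endswith("rot90")
        # Layers touch vertically so the occupied region has height 3 dm
        # (3 um for dm = 1 um, matching the standing-body models).
        offsets = _seven_layer_centers(lm, dm, gap)
        centrals_list = []
        for layer in range(3):  # layer 0 = bottom, 2 = top
            z = floor_z - dm / 2.0 - layer * dm
            az = 90.0 if (rot90_middle and layer == 1) else 0.0
            for j, (x, y) in enumerate(offsets):
                if j == 0:
                    centrals_list.append(len(ells))
                if az == 90.0:
                    x, y = -y, x
                ells.append(_horizontal(x, y, z, az, lm, dm, mito_medium))
        # report top, center, bottom centrals in that order
        centrals = (centrals_list[2], centrals_list[1], centrals_list[0])
    elif kind == "periodic_array":
        nx, ny = array_shape
        if nx < 1 or ny < 1 or nx % 2 == 0 or ny % 2 == 0:
            raise ValueError("array_shape must be odd x odd so a central cell exists")
        px, py = lm + gap, dm + gap
        centrals_idx = None
        for iy in range(ny):
            for ix in range(nx):
                x = (ix - (nx - 1) / 2.0) * px
                y = (iy - (ny - 1) / 2.0) * py
                if abs(x) < px / 4 and abs(y) < py / 4:
                    centrals_idx = len(ells)
                ells.append(_horizontal(x, y, zc, 0, lm, dm, mito_medium))
        centrals = (centrals_idx,)

    scene = Scene(ells, bg, floor_z=floor_z, label=kind, central_indices=centrals)
    scene.validate()
    return scene


def random_scene(
    n: int,
    lambda0: float = 980e-9,
    dm: float = DEFAULT_DM,
    lm: float = DEFAULT_LM,
    seed: int = 0,
    region_radius: float = 20e-6,
    mito_medium: Medium | None = None,
    max_tries: int = 2000,
    floor_z: float = FLOOR_Z,
) -> Scene:
    """n non-overlapping horizontal mitochondria with random in-plane
    positions and azimuths, resting on the floor; deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mito_medium is None:
        mito_medium = mitochondrion_medium(lambda0)
    bg = medium_lookup("saline", lambda0)
    rng = np.random.default_rng(seed)
    zc = floor_z - dm / 2.0
    placed: list[Ellipsoid] = []
    polys: list[Polygon] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise GeometryError(
                f"could not place {n} bodies in radius {region_radius} after {max_tries} tries"
            )
        tries += 1
        rr = region_radius * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        az = rng.uniform(0, 180.0)
        cand = _horizontal(rr * math.cos(th), rr * math.sin(th), zc, az, lm, dm, mito_medium)
        poly = cand.plan_polygon()
        if any(poly.intersects(p) for p in polys):
            continue
        placed.append(cand)
        polys.append(poly)
    scene = Scene(placed, bg, floor_z=floor_z, label=f"random_n{n}_seed{seed}", central_indices=(0,))
    scene.validate()
    return scene


@dataclass
class DipoleGrid:
    """Voxelization of a scene on a regular cubic lattice.

    Only voxels whose centers fall strictly inside some ellipsoid are
    occupied.  ``indices`` are integer lattice coordinates into a
    bounding box of ``shape`` voxels with origin ``origin`` (the center
    of voxel (0,0,0)); ``owner`` maps each occupied voxel to its
    ellipsoid.
    """

    scene: Scene
    spacing: float
    origin: np.ndarray  # (3,)
    shape: tuple[int, int, int]
    indices: np.ndarray  # (N, 3) int
    owner: np.ndarray  # (N,) int

    @property
    def n_dipoles(self) -> int:
        return len(self.owner)

    @property
    def positions(self) -> np.ndarray:
        return self.origin[None, :] + self.indices * self.spacing

    def owner_volume(self, owner_index: int) -> float:
        return float(np.count_nonzero(self.owner == owner_index)) * self.spacing**3

    def eps_contrast(self) -> np.ndarray:
        """Per-voxel relative permittivity of the occupying medium."""
        from .media import permittivity

        eps_by_owner = np.array(
            [permittivity(e.medium).eps_complex for e in self.scene.ellipsoids]
        )
        return eps_by_owner[self.owner]


def voxelize(scene: Scene, spacing: float) -> DipoleGrid:
    """Voxelize a scene; raises if the spacing cannot resolve the bodies
    (coarser than dm/4)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if scene.ellipsoids:
        dmin = min(e.dm for e in scene.ellipsoids)
        if spacing > dmin / 4.0:
            raise ValueError(
                f"spacing {spacing:g} m coarser than dm/4 = {dmin/4:g} m"
            )
    if not scene.ellipsoids:
        return DipoleGrid(
            scene,
            spacing,
            np.zeros(3),
            (0, 0, 0),
            np.zeros((0, 3), dtype=int),
            np.zeros(0, dtype=int),
        )
    lo = np.min(
        [np.asarray(e.center) - e.half_extents() - spacing for e in scene.ellipsoids],
        axis=0,
    )
    hi = np.max(
        [np.asarray(e.center) + e.half_extents() + spacing for e in scene.ellipsoids],
        axis=0,
    )
    shape = tuple(np.maximum(1, np.ceil((hi - lo) / spacing).astype(int)))
    origin = lo + spacing / 2.0
    ax = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    owner_grid = np.full(shape, -1, dtype=np.int32)
    for idx, e in enumerate(scene.ellipsoids):
        c = np.asarray(e.center)
        he = e.half_extents()
        sub = []
        for d in range(3):
            half = he[d] + spacing
            i0 = int(np.searchsorted(ax[d], c[d] - half))
            i1 = int(np.searchsorted(ax[d], c[d] + half))
            sub.append((i0, i1))
        (x0, x1), (y0, y1), (z0, z1) = sub
        X, Y, Z = np.meshgrid(
            ax[0][x0:x1], ax[1][y0:y1], ax[2][z0:z1], indexing="ij"
        )
        pts = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
        mask = e.contains(pts).reshape(X.shape)
        owner_grid[x0:x1, y0:y1, z0:z1][mask] = idx
    occ = np.argwhere(owner_grid >= 0)
    owner = owner_grid[occ[:, 0], occ[:, 1], occ[:, 2]]
    return DipoleGrid(scene, spacing, origin, shape, occ, owner)
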