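"""Detector and source geometry for the six-crystal rotating Compton camera.

Six cubic scintillator crystals sit at the vertices of an octahedron of side
length ``W`` cm, i.e. at distance ``W/sqrt(2)`` from the origin on the +/-x,
+/-y and +/-z axes.  The cube size scales as ``3.5 * (W/10)`` cm unless
overridden (the crystal-interval study keeps 3.5 cm cubes while shrinking W).

Coordinate convention (right-handed): +x is azimuth 0 deg, elevation 0 deg;
azimuth increases counterclockwise seen from +z; elevation is latitude.
Detector rotation is emulated per event by rotating the *source* by a uniform
angle theta_rot about the vertical (z) axis at emission time and rotating the
crystal coordinates by -theta_rot at reconstruction time; the round trip is
the identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import Material, builtin_material

__all__ = [
    "DetectorModel",
    "SourceModel",
    "VialSpec",
    "build_detector",
    "rotate_event_frame",
    "emission_sampler",
    "direction_from_angles",
    "angles_from_direction",
    "GeometryError",
]

PMT_SIZE_CM = (3.3, 3.3, 5.0)  # metal-packaged PMT modelled as an aluminum box

# emission ratio eta_gamma (photons per decay) for the studied lines
EMISSION_RATIOS = {113.0: 0.064, 141.0: 0.89, 208.0: 0.11, 511.0: 2.00, 1333.0: 1.00}


class GeometryError(ValueError):
    pass


def direction_from_angles(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector for (azimuth, elevation) in degrees."""
    az = math.radians(azimuth_deg)
    el = math.radians(elevation_deg)
    return np.array([math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)])

def angles_from_direction(v) -> tuple[float, float]:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    el = math.degrees(math.asin(v[2] / n))
    az = math.degrees(math.atan2(v[1], v[0]))
    return az, el


@dataclass(frozen=True)
class DetectorModel:
    """Six cubic crystals at octahedron vertices, optional PMT blocks."""

    W: float = 10.0  # octahedron side length, cm
    crystal_size: float = 3.5  # cube side, cm
    material: Material = field(default_factory=lambda: builtin_material("CaF2"))
    with_pmts: bool = False
    pmt_layout: str = "radial"  # "radial": behind each crystal; "vertical": below

    @property
    def center_distance(self) -> float:
        return self.W / math.sqrt(2.0)

    @property
    def crystal_centers(self) -> np.ndarray:
        d = self.center_distance
        return np.array(
            [[d, 0, 0], [-d, 0, 0], [0, d, 0], [0, -d, 0], [0, 0, d], [0, 0, -d]],
            dtype=float,
        )

    def crystal_boxes(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners, shape (6, 3), axis-aligned cubes."""
        h = self.crystal_size / 2.0
        c = self.crystal_centers
        return c - h, c + h

    def pmt_boxes(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) corners of the aluminum PMT blocks (empty if disabled)."""
        if not self.with_pmts:
            return np.zeros((0, 3)), np.zeros((0, 3))
        sx, sy, sz = PMT_SIZE_CM
        half = self.crystal_size / 2.0
        centers = self.crystal_centers
        lo = np.empty((6, 3))
        hi = np.empty((6, 3))
        for i, c in enumerate(centers):
            if self.pmt_layout == "vertical":
                axis = np.array([0.0, 0.0, -1.0])
            else:  # flush to the face pointing away from the detector center
                axis = c / np.linalg.norm(c)
                axis = np.sign(np.round(axis))  # centers are axial, keep it exact
            # long (5 cm) dimension along the coupling axis
            size = np.where(axis != 0, sz, sx)
            pc = c + axis * (half + sz / 2.0)
            lo[i] = pc - size / 2.0
            hi[i] = pc + size / 2.0
        return lo, hi

    @property
    def bounding_radius(self) -> float:
        los, his = self.crystal_boxes()
        r = max(np.linalg.norm(his, axis=1).max(), np.linalg.norm(los, axis=1).max())
        if self.with_pmts:
            lo, hi = self.pmt_boxes()
            corners = np.concatenate([lo, hi])
            r = max(r, np.linalg.norm(corners, axis=1).max())
        return float(r)


def build_detector(
    W: float = 10.0,
    material: Material | str = "CaF2",
    crystal_size: float | None = None,
    with_pmts: bool = False,
    pmt_layout: str = "radial",
) -> DetectorModel:
    """Build the octahedral detector; cube side defaults to 3.5*(W/10) cm."""
    if W <= 0:
        raise GeometryError("octahedron side length W must be positive")
    if pmt_layout not in ("radial", "vertical"):
        raise GeometryError(f"unknown pmt_layout {pmt_layout!r}")
    size = 3.5 * (W / 10.0) if crystal_size is None else float(crystal_size)
    if size <= 0:
        raise GeometryError("crystal size must be positive")
    # adjacent vertices are W apart; opposite vertices 2*W/sqrt(2).  Adjacent
    # axis-aligned cubes of side s centred at (d,0,0) and (0,d,0) overlap iff
    # s > d = W/sqrt(2).
    if size > W / math.sqrt(2.0) + 1e-12:
        raise GeometryError(
            f"crystal cubes of {size} cm overlap at interval W={W} cm "
            f"(maximum non-overlapping size {W / math.sqrt(2.0):.3f} cm)"
        )
    if isinstance(material, str):
        material = builtin_material(material)
    return DetectorModel(W=W, crystal_size=size, material=material,
                         with_pmts=with_pmts, pmt_layout=pmt_layout)


@dataclass(frozen=True)
class VialSpec:
    """Cylindrical borosilicate vial holding the liquid source."""

    outer_diameter: float = 3.15  # cm
    inner_diameter: float = 2.85  # cm
    height: float = 4.3  # cm, outer
    wall: float = 0.15  # cm, side wall = (OD-ID)/2; also bottom/top thickness
    water_volume_ml: float = 25.0

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def fill_height(self) -> float:
        h = self.water_volume_ml / (math.pi * self.inner_radius**2)
        if h > self.height - 2 * self.wall:
            raise GeometryError("water volume exceeds the vial's inner cavity")
        return h


@dataclass(frozen=True)
class SourceModel:
    """Gamma source: isotropic point, or water volume inside a glass vial."""

    kind: str = "point"  # "point" | "vial"
    position: tuple[float, float, float] = (-100.0, 0.0, 0.0)  # cm
    energy: float = 208.0  # keV
    emission_ratio: float | None = None  # photons/decay; looked up if None
    vial: VialSpec = field(default_factory=VialSpec)

    def __post_init__(self) -> None:
        if self.kind not in ("point", "vial"):
            raise GeometryError(f"unknown source kind {self.kind!r}")

    @property
    def eta_gamma(self) -> float:
        if self.emission_ratio is not None:
            return self.emission_ratio
        try:
            return EMISSION_RATIOS[float(self.energy)]
        except KeyError:
            raise GeometryError(
                f"no built-in emission ratio for {self.energy} keV; set emission_ratio"
            ) from None

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.position))


def rotate_event_frame(point, theta_rot_deg: float, direction: str = "forward") -> np.ndarray:
    """Rotate about the vertical (z) axis; ``inverse`` undoes ``forward``.

    ``forward`` rotates by +theta_rot (counterclockwise seen from +z), the
    rotation applied to the source at emission time; reconstruction applies
    ``inverse`` (-theta_rot) to the crystal coordinates.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    t = math.radians(theta_rot_deg)
    if direction == "inverse":
        t = -t
    c, s = math.cos(t), math.sin(t)
    p = np.asarray(point, dtype=float)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return p @ rot.T


def cap_solid_angle_fraction(half_angle_deg: float) -> float:
    """Fraction of the full sphere covered by a cap of the given half-angle."""
    return (1.0 - math.cos(math.radians(half_angle_deg))) / 2.0


def emission_sampler(
    source: SourceModel,
    rng: np.random.Generator,
    n: int,
    cone_half_angle_deg: float | None = None,
    detector: DetectorModel | None = None,
):
    """Sample emission origins and directions.

    Directions are uniform on the sphere, or uniform on the spherical cap of
    the given half-angle aimed from the source at the detector origin.  The
    returned solid-angle fraction ``f`` makes importance-sampled sensitivity
    estimates unbiased: ``C0_effective = n_emitted / f``.

    Returns ``(origins (n,3), directions (n,3), f)``.
    """
    pos = np.asarray(source.position, dtype=float)
    if source.kind == "point":
        origins = np.broadcast_to(pos, (n, 3)).copy()
    else:
        v = source.vial
        r = v.inner_radius * np.sqrt(rng.random(n))
        phi = 2 * np.pi * rng.random(n)
        z = v.wall + v.fill_height * rng.random(n)  # vial base sits at z=0 locally
        local = np.column_stack([r * np.cos(phi), r * np.sin(phi), z - v.height / 2.0])
        origins = pos + local  # vial centred (vertically) on the source position

    if cone_half_angle_deg is None:
        f = 1.0
        cos_t = 1.0 - 2.0 * rng.random(n)
    else:
        if detector is not None:
            dist = float(np.linalg.norm(pos))
            needed = math.degrees(math.asin(min(1.0, detector.bounding_radius / dist)))
            if cone_half_angle_deg < needed:
                raise GeometryError(
                    f"emission cone of {cone_half_angle_deg:.2f} deg clips the detector "
                    f"(needs >= {needed:.2f} deg from {dist:.0f} cm)"
                )
        f = cap_solid_angle_fraction(cone_half_angle_deg)
        cmin = math.cos(math.radians(cone_half_angle_deg))
        cos_t = 1.0 - (1.0 - cmin) * rng.random(n)
    phi = 2 * np.pi * rng.random(n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    local_dirs = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    if cone_half_angle_deg is None:
        return origins, local_dirs, f  # already uniform on the sphere
    # rotate the cap axis (+z locally) onto the source->origin direction
    axis = -pos / np.linalg.norm(pos)
    dirs = _rotate_z_to(local_dirs, axis)
    return origins, dirs, f


def _rotate_z_to(vectors: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Rotate vectors expressed about +z so that +z maps onto ``axis``."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1 - 1e-12:
        return vectors
    if c < -1 + 1e-12:
        return vectors * np.array([1.0, -1.0, -1.0])
    k = np.cross(z, axis)
    k /= np.linalg.norm(k)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + math.sqrt(1 - c * c) * kx + (1 - c) * (kx @ kx)
    return vectors @ rot.T
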