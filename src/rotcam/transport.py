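"""Monte Carlo photon transport through the rotated six-crystal detector.

The heavy lifting happens in :mod:`rotcam._kernel` (numba); this module
prepares geometry/material arrays, manages seeds and emission accounting,
and exposes the simulation operations:

* :func:`transport_photon` -- one photon, one raw history (mostly for tests
  and pedagogy),
* :func:`simulate_listmode` -- batched histories with per-event source
  rotation and cone importance sampling, returning raw coincidence material
  plus the effective isotropic-emission count ``C0`` used by the sensitivity
  estimator,
* :func:`self_absorption_fraction` -- attenuation line-integral estimate of
  the fraction of photons interacting in the water/glass of a source vial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .geometry import DetectorModel, SourceModel, GeometryError, cap_solid_angle_fraction
from .materials import Material, builtin_material

__all__ = [
    "RawHistory",
    "HistoryBatch",
    "transport_photon",
    "simulate_listmode",
    "self_absorption_fraction",
    "CONE_MARGIN",
]

CONE_MARGIN = 1.2  # importance-sampling cone = margin x detector angular radius
TABLE_GRID = (10.0, 2000.0, 256)  # keV bounds and points of the kernel tables


@dataclass(frozen=True)
class RawHistory:
    """True (unsmeared) per-crystal deposits of one photon history."""

    theta_rot: float  # degrees
    deposits: np.ndarray  # (6,) keV
    interaction_counts: np.ndarray  # (6,)

    @property
    def hit_crystals(self) -> np.ndarray:
        return np.flatnonzero(self.deposits > 0)


@dataclass
class HistoryBatch:
    """Columnar batch of recorded histories plus emission accounting.

    ``c0_effective`` is the number of isotropic emissions the run is
    equivalent to: emitted photons divided by the sampled solid-angle
    fraction.  Sensitivities are ``counts / c0_effective``.
    """

    theta_rot: np.ndarray  # (m,) degrees
    deposits: np.ndarray  # (m, 6) keV
    n_emitted: int
    solid_angle_fraction: float
    seed: int
    energy: float
    flags: dict = field(default_factory=dict)

    @property
    def c0_effective(self) -> float:
        return self.n_emitted / self.solid_angle_fraction

    @property
    def n_hit_crystals(self) -> np.ndarray:
        return (self.deposits > 0).sum(axis=1)

    def twofold(self) -> "HistoryBatch":
        """Histories whose true deposits touched exactly two crystals."""
        keep = self.n_hit_crystals == 2
        return HistoryBatch(self.theta_rot[keep], self.deposits[keep],
                            self.n_emitted, self.solid_angle_fraction,
                            self.seed, self.energy, dict(self.flags))

    def extend(self, other: "HistoryBatch") -> None:
        self.theta_rot = np.concatenate([self.theta_rot, other.theta_rot])
        self.deposits = np.concatenate([self.deposits, other.deposits])
        self.n_emitted += other.n_emitted


class _KernelArgs:
    """Flattened geometry + material tables for the numba kernel."""

    def __init__(self, detector: DetectorModel):
        c_lo, c_hi = detector.crystal_boxes()
        p_lo, p_hi = detector.pmt_boxes()
        self.lo = np.ascontiguousarray(np.concatenate([c_lo, p_lo]))
        self.hi = np.ascontiguousarray(np.concatenate([c_hi, p_hi]))
        npmt = p_lo.shape[0]
        self.box_crystal = np.concatenate(
            [np.arange(6, dtype=np.int64), -np.ones(npmt, dtype=np.int64)]
        )
        mats = [detector.material] + ([builtin_material("aluminum")] if npmt else [])
        self.box_mat = np.concatenate(
            [np.zeros(6, dtype=np.int64), np.ones(npmt, dtype=np.int64)]
        )
        e0, e1, ng = TABLE_GRID
        grid = np.geomspace(e0, e1, ng)
        self.log_e0 = math.log(e0)
        self.inv_dlog = (ng - 1) / (math.log(e1) - math.log(e0))
        self.ng = ng
        self.log_mu_pe = np.empty((len(mats), ng))
        self.log_mu_inc = np.empty((len(mats), ng))
        for i, m in enumerate(mats):
            self.log_mu_pe[i] = np.log(np.maximum(m.mu(grid, "photoelectric"), 1e-30))
            self.log_mu_inc[i] = np.log(np.maximum(m.mu(grid, "incoherent"), 1e-30))
        self.escape_r2 = (detector.bounding_radius + 1.0) ** 2

    def tuple(self):
        return (self.lo, self.hi, self.box_crystal, self.box_mat,
                self.log_mu_pe, self.log_mu_inc,
                self.log_e0, self.inv_dlog, self.ng, self.escape_r2)


def _as_seed(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _kernel_seed(ss: np.random.SeedSequence) -> np.uint64:
    return np.uint64(ss.generate_state(1, dtype=np.uint64)[0])


def transport_photon(
    detector: DetectorModel,
    origin,
    direction,
    energy: float,
    seed: int = 0,
) -> RawHistory:
    """Transport a single photon and return its raw history."""
    lo, hi, _ = TABLE_GRID
    if not (lo <= energy <= hi):
        raise ValueError(f"energy {energy} keV outside the cross-section grid [{lo}, {hi}]")
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if abs(n - 1.0) > 1e-9:
        warnings.warn("non-unit direction normalized", stacklevel=2)
        d = d / n
    args = _KernelArgs(detector)
    dep, counts = _kernel.transport_single(
        _kernel_seed(_as_seed(seed)), np.asarray(origin, dtype=float), d, float(energy),
        *args.tuple(),
    )
    return RawHistory(0.0, dep, counts)


def simulate_listmode(
    detector: DetectorModel,
    source: SourceModel,
    n_histories: int | None = None,
    target_coincidences: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    importance_cone: bool = True,
    rotate_source: bool = True,
    max_histories: int = 500_000_000,
    batch: int = 2_000_000,
) -> HistoryBatch:
    """Simulate list-mode histories for a point source.

    Each event draws theta_rot ~ U[0, 360), rotates the source forward by it,
    emits a photon (isotropically, or uniformly over an importance cone that
    covers the detector with a margin) and transports it.  Histories with at
    least one nonzero crystal deposit are recorded.

    Exactly one of ``n_histories`` (photons to emit) or
    ``target_coincidences`` (exactly-two-crystal histories to collect) must
    be given.  If the target is not reached within ``max_histories`` the
    partial result is returned with ``flags['partial'] = True``.
    """
    if (n_histories is None) == (target_coincidences is None):
        raise ValueError("give exactly one of n_histories / target_coincidences")
    if source.kind != "point":
        raise ValueError("simulate_listmode transports point sources; "
                         "use self_absorption_fraction for vial sources")
    dist = source.distance
    if importance_cone:
        half = CONE_MARGIN * math.degrees(math.asin(min(1.0, detector.bounding_radius / dist)))
        if half >= 90.0:
            raise GeometryError("source too close for cone importance sampling")
        f = cap_solid_angle_fraction(half)
        cone_cos = math.cos(math.radians(half))
    else:
        f = 1.0
        cone_cos = -2.0
    args = _KernelArgs(detector)
    ss = _as_seed(seed)
    src = np.asarray(source.position, dtype=float)

    rot_parts, dep_parts = [], []
    n_emitted = 0
    n_two = 0
    lines = 0
    while True:
        if n_histories is not None:
            todo = n_histories - n_emitted
            if todo <= 0:
                break
            this = min(todo, batch)
        else:
            if n_two >= target_coincidences or n_emitted >= max_histories:
                break
            this = min(batch, max_histories - n_emitted)
        cap = max(1024, this // 4)
        out_rot = np.empty(cap)
        out_dep = np.empty((cap, 6))
        kseed = _kernel_seed(ss.spawn(1)[0])
        n_done, m = _kernel.run_histories(
            kseed, this, src, float(source.energy), cone_cos, rotate_source,
            *args.tuple(), out_rot, out_dep,
        )
        n_emitted += int(n_done)
        rot_parts.append(out_rot[:m].copy())
        dep_parts.append(out_dep[:m].copy())
        n_two += int(((out_dep[:m] > 0).sum(axis=1) == 2).sum())
        lines += 1
        if lines > 10000:  # pragma: no cover - safety valve
            break

    rot = np.concatenate(rot_parts) if rot_parts else np.empty(0)
    dep = np.concatenate(dep_parts) if dep_parts else np.empty((0, 6))
    flags = {}
    if target_coincidences is not None and n_two < target_coincidences:
        flags["partial"] = True
        warnings.warn(
            f"only {n_two}/{target_coincidences} twofold histories within "
            f"{n_emitted} emissions", stacklevel=2,
        )
    return HistoryBatch(rot, dep, n_emitted, f,
                        seed=int(ss.entropy) if isinstance(ss.entropy, int) else 0,
                        energy=float(source.energy), flags=flags)


def _cylinder_exit(p: np.ndarray, d: np.ndarray, radius: float, z0: float, z1: float) -> np.ndarray:
    """Distance to exit a finite cylinder from interior points (vectorized)."""
    # radial quadratic: |p_xy + t d_xy|^2 = radius^2, take positive root
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1]
    c = p[:, 0] ** 2 + p[:, 1] ** 2 - radius**2
    disc = np.sqrt(np.maximum(b * b - a * c, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_rad = np.where(a > 0, (-b + disc) / a, np.inf)
    t_cap = np.where(
        d[:, 2] > 0, (z1 - p[:, 2]) / np.where(d[:, 2] == 0, 1.0, d[:, 2]),
        np.where(d[:, 2] < 0, (z0 - p[:, 2]) / np.where(d[:, 2] == 0, 1.0, d[:, 2]), np.inf),
    )
    return np.minimum(t_rad, t_cap)


def self_absorption_fraction(
    source: SourceModel,
    energy: float | None = None,
    n: int = 200_000,
    rng: np.random.Generator | int | None = 0,
    water: Material | None = None,
    glass: Material | None = None,
) -> float:
    """Fraction of photons interacting in the vial liquid or glass.

    Origins are uniform in the water volume, directions isotropic; the
    interaction probability along each escape ray is
    ``1 - exp(-mu_w L_water - mu_g L_glass)`` with path lengths computed
    analytically through the water column and the glass shell.
    """
    if source.kind != "vial":
        raise ValueError("self-absorption is defined for vial sources")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    e = float(source.energy if energy is None else energy)
    water = water or builtin_material("water")
    glass = glass or builtin_material("borosilicate")
    mu_w = float(water.mu(e, "total"))
    mu_g = float(glass.mu(e, "total"))

    v = source.vial
    # local frame: vial axis = z, outer base at z=0
    r = v.inner_radius * np.sqrt(rng.random(n))
    phi = 2 * np.pi * rng.random(n)
    z = v.wall + v.fill_height * rng.random(n)
    p = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    ct = 1.0 - 2.0 * rng.random(n)
    st = np.sqrt(1.0 - ct**2)
    dphi = 2 * np.pi * rng.random(n)
    d = np.column_stack([st * np.cos(dphi), st * np.sin(dphi), ct])

    l_water = _cylinder_exit(p, d, v.inner_radius, v.wall, v.wall + v.fill_height)
    l_cavity = _cylinder_exit(p, d, v.inner_radius, v.wall, v.height - v.wall)
    l_outer = _cylinder_exit(p, d, v.outer_radius, 0.0, v.height)
    l_glass = np.maximum(l_outer - l_cavity, 0.0)
    p_int = 1.0 - np.exp(-mu_w * l_water - mu_g * l_glass)
    return float(p_int.mean())
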