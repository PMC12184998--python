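"""Photon interaction data for the detector, source container and shielding.

Per-element mass attenuation coefficients (photoelectric and incoherent,
coherent scattering omitted by design) are shipped as columnar text fixtures
under :mod:`rotcam.data` and interpolated log-log.  Compounds are mixtures by
mass fraction; the linear attenuation coefficient is

    mu(E) = rho * sum_i w_i * (mu/rho)_i(E)   [1/cm]

which is all the transport and self-absorption Monte Carlo needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "ElementTable",
    "Material",
    "load_element",
    "attenuation_coefficient",
    "mean_free_path_sample",
    "builtin_material",
    "BUILTIN_MATERIALS",
    "TransparentMaterialError",
]

PROCESSES = ("photoelectric", "incoherent", "total")


class TransparentMaterialError(ValueError):
    """Raised when a mean free path is requested in a medium with mu = 0."""


@dataclass(frozen=True)
class ElementTable:
    """Cross-section table for one element on an ascending energy grid."""

    symbol: str
    atomic_number: int
    energy_grid: np.ndarray  # keV, strictly ascending
    photoelectric_xs: np.ndarray  # cm^2/g
    incoherent_xs: np.ndarray  # cm^2/g

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.energy_grid) > 0):
            raise ValueError(f"{self.symbol}: energy grid must be strictly ascending")
        if np.any(self.photoelectric_xs < 0) or np.any(self.incoherent_xs < 0):
            raise ValueError(f"{self.symbol}: cross sections must be non-negative")

    def mu_rho(self, energy_kev: float | np.ndarray, process: str = "total") -> np.ndarray:
        """Mass attenuation coefficient (cm^2/g), log-log interpolated."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energy_grid[0], self.energy_grid[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside table range [{lo:g}, {hi:g}] keV for element {self.symbol}"
            )
        loge = np.log(e)
        logg = np.log(self.energy_grid)
        out = 0.0
        if process in ("photoelectric", "total"):
            out = out + _loglog_interp(loge, logg, self.photoelectric_xs)
        if process in ("incoherent", "total"):
            out = out + _loglog_interp(loge, logg, self.incoherent_xs)
        if process not in PROCESSES:
            raise ValueError(f"unknown process {process!r}; expected one of {PROCESSES}")
        return out


def _loglog_interp(loge: np.ndarray, log_grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    # zeros in a log table are clamped to a tiny floor; they only occur for
    # numerically negligible channels
    logv = np.log(np.maximum(values, 1e-300))
    return np.exp(np.interp(loge, log_grid, logv))


@lru_cache(maxsize=None)
def load_element(symbol: str) -> ElementTable:
    """Load one element's fixture table shipped with the package."""
    try:
        text = (resources.files("rotcam.data") / f"{symbol}.txt").read_text()
    except FileNotFoundError:
        raise KeyError(f"no cross-section table for element {symbol!r}") from None
    z = None
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("#"):
            if "Z=" in line:
                z = int(line.split("Z=")[1].split()[0])
            continue
        if line:
            rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows)
    return ElementTable(symbol, int(z), arr[:, 0], arr[:, 1], arr[:, 2])


@dataclass(frozen=True)
class Material:
    """A compound or mixture: mass fractions per element plus bulk density."""

    name: str
    mass_fractions: dict = field(default_factory=dict)  # element symbol -> fraction
    density: float = 1.0  # g/cm^3

    def __post_init__(self) -> None:
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mass fractions sum to {total}, expected 1")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")

    def mu_rho(self, energy_kev, process: str = "total") -> np.ndarray:
        out = 0.0
        for sym, w in self.mass_fractions.items():
            out = out + w * load_element(sym).mu_rho(energy_kev, process)
        return out

    def mu(self, energy_kev, process: str = "total") -> np.ndarray:
        return self.density * self.mu_rho(energy_kev, process)


def attenuation_coefficient(material: Material, energy_kev, process: str = "total"):
    """Linear attenuation coefficient in 1/cm for the given process."""
    if process not in PROCESSES:
        raise ValueError(f"unknown process {process!r}; expected one of {PROCESSES}")
    return material.mu(energy_kev, process)


def mean_free_path_sample(material: Material, energy_kev: float, rng: np.random.Generator, size=None):
    """Sample photon path lengths (cm) from the exponential free-flight law."""
    mu = float(material.mu(energy_kev, "total"))
    if mu <= 0:
        raise TransparentMaterialError(f"{material.name} is transparent at {energy_kev} keV")
    return rng.exponential(1.0 / mu, size=size)


def _frac(pairs: dict[str, float]) -> dict[str, float]:
    s = sum(pairs.values())
    return {k: v / s for k, v in pairs.items()}


# oxide -> element decomposition for borosilicate glass (mass fractions)
def _borosilicate_fractions() -> dict[str, float]:
    oxides = {"SiO2": 0.80, "B2O3": 0.13, "Na2O": 0.04, "Al2O3": 0.03}
    masses = {
        "SiO2": {"Si": 28.086, "O": 2 * 15.999},
        "B2O3": {"B": 2 * 10.811, "O": 3 * 15.999},
        "Na2O": {"Na": 2 * 22.990, "O": 15.999},
        "Al2O3": {"Al": 2 * 26.982, "O": 3 * 15.999},
    }
    out: dict[str, float] = {}
    for ox, w in oxides.items():
        total = sum(masses[ox].values())
        for el, m in masses[ox].items():
            out[el] = out.get(el, 0.0) + w * m / total
    return _frac(out)


BUILTIN_MATERIALS: dict[str, Material] = {
    "CsI": Material("CsI", _frac({"Cs": 132.905, "I": 126.904}), 4.51),
    "NaI": Material("NaI", _frac({"Na": 22.990, "I": 126.904}), 3.67),
    "CaF2": Material("CaF2", _frac({"Ca": 40.078, "F": 2 * 18.998}), 3.19),
    "water": Material("water", _frac({"H": 2 * 1.008, "O": 15.999}), 1.0),
    "aluminum": Material("aluminum", {"Al": 1.0}, 2.70),
    "borosilicate": Material("borosilicate", _borosilicate_fractions(), 2.23),
}


def builtin_material(name: str) -> Material:
    try:
        return BUILTIN_MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; built-ins: {sorted(BUILTIN_MATERIALS)}"
        ) from None
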