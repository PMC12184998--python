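"""File formats and run configuration.

Canonical list-mode format: tab-separated columns with ``#``-prefixed header
metadata lines (``key: value``), human-diffable and lossless on round trip.
Sky maps are written the same way (90x180 matrix, one elevation row per
line).  Run configurations are YAML with strict (unknown keys rejected)
validation.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .recon import SkyMap

__all__ = [
    "write_listmode",
    "read_listmode",
    "write_skymap",
    "read_skymap",
    "RunConfig",
    "load_config",
    "config_hash",
    "render_skymap_png",
]

FORMAT_VERSION = "1"


def _write_header(fh, meta: dict) -> None:
    fh.write(f"# format_version: {FORMAT_VERSION}\n")
    for k, v in meta.items():
        fh.write(f"# {k}: {json.dumps(v) if not isinstance(v, str) else v}\n")


def _read_header(path) -> tuple[dict, int]:
    meta = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line[1:].strip()
            if ": " in body:
                k, v = body.split(": ", 1)
                try:
                    meta[k] = json.loads(v)
                except (json.JSONDecodeError, ValueError):
                    meta[k] = v
    return meta, n


def write_listmode(path, events: pd.DataFrame, meta: dict | None = None) -> None:
    """Write list-mode events (columnar text, '#' header)."""
    path = pathlib.Path(path)
    cols = list(events.columns)
    with path.open("w") as fh:
        _write_header(fh, meta or {})
        fh.write("# columns: " + "\t".join(cols) + "\n")
        events[cols].to_csv(fh, sep="\t", index=False, header=False,
                            float_format="%.6f")


def read_listmode(path) -> tuple[pd.DataFrame, dict]:
    meta, nskip = _read_header(path)
    cols = str(meta.pop("columns")).split("\t")
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=nskip, names=cols)
    for c in ("crystal_a", "crystal_b", "scatterer", "absorber", "event_id"):
        if c in df.columns:
            df[c] = df[c].astype(np.int64)
    if "crystal_a" in df.columns:
        bad = ~df["crystal_a"].between(0, 5) | ~df["crystal_b"].between(0, 5)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} events with crystal indices outside 0-5")
    return df, meta


def write_skymap(path, sky: SkyMap, meta: dict | None = None) -> None:
    path = pathlib.Path(path)
    with path.open("w") as fh:
        _write_header(fh, {**sky.meta, **(meta or {}),
                           "radius_cm": sky.radius_cm, "bin_deg": sky.bin_deg,
                           "shape": list(sky.data.shape)})
        np.savetxt(fh, sky.data, fmt="%.8e", delimiter="\t")


def read_skymap(path) -> SkyMap:
    meta, nskip = _read_header(path)
    data = np.loadtxt(path, skiprows=nskip, delimiter="\t")
    return SkyMap(data=data, radius_cm=float(meta.pop("radius_cm", 100.0)),
                  bin_deg=float(meta.pop("bin_deg", 2.0)), meta=meta)


def render_skymap_png(path, sky: SkyMap, contour_fraction: float = 0.70) -> None:
    """Raster render with the >=70%-of-peak region contoured in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.2))
    extent = [-180, 180, -90, 90]
    im = ax.imshow(sky.data, origin="lower", extent=extent, aspect="auto", cmap="viridis")
    peak = sky.data.max()
    if peak > 0:
        ax.contour(sky.azimuth_centers, sky.elevation_centers, sky.data,
                   levels=[contour_fraction * peak], colors="red")
    ax.set_xlabel("azimuth [deg]")
    ax.set_ylabel("elevation [deg]")
    fig.colorbar(im, ax=ax, label="intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# run configuration

_GEOMETRY_KEYS = {"W_cm", "crystal_size_cm", "material", "with_pmts", "pmt_layout"}
_SOURCE_KEYS = {"kind", "azimuth_deg", "elevation_deg", "distance_cm", "energy_kev",
                "emission_ratio"}
_CUT_KEYS = {"tdc_ns", "adc_nsigma", "threshold_kev", "ordering"}
_KERNEL_KEYS = {"kind", "sigma_deg", "k"}
_MAP_KEYS = {"radius_cm"}


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults are the studied baseline."""

    geometry: dict = field(default_factory=lambda: {
        "W_cm": 10.0, "crystal_size_cm": None, "material": "CaF2",
        "with_pmts": False, "pmt_layout": "radial"})
    source: dict = field(default_factory=lambda: {
        "kind": "point", "azimuth_deg": 0.0, "elevation_deg": 0.0,
        "distance_cm": 100.0, "energy_kev": 208.0, "emission_ratio": None})
    cuts: dict = field(default_factory=lambda: {
        "tdc_ns": 400.0, "adc_nsigma": 3.0, "threshold_kev": 10.0,
        "ordering": "kinematic"})
    kernel: dict = field(default_factory=lambda: {
        "kind": "sharpening", "sigma_deg": 8.0, "k": 1.0})
    map: dict = field(default_factory=lambda: {"radius_cm": 100.0})
    seed: int = 0
    n_histories: int | None = None
    target_coincidences: int | None = 10000

    def __post_init__(self) -> None:
        for name, block, allowed in (
            ("geometry", self.geometry, _GEOMETRY_KEYS),
            ("source", self.source, _SOURCE_KEYS),
            ("cuts", self.cuts, _CUT_KEYS),
            ("kernel", self.kernel, _KERNEL_KEYS),
            ("map", self.map, _MAP_KEYS),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
        if self.cuts.get("adc_nsigma") not in (2, 2.0, 3, 3.0):
            raise ValueError("adc_nsigma must be 2 or 3")

    def detector(self):
        from .geometry import build_detector

        g = self.geometry
        return build_detector(W=g.get("W_cm", 10.0), material=g.get("material", "CaF2"),
                              crystal_size=g.get("crystal_size_cm"),
                              with_pmts=g.get("with_pmts", False),
                              pmt_layout=g.get("pmt_layout", "radial"))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    base = RunConfig()
    for blk in ("geometry", "source", "cuts", "kernel", "map"):
        if blk in raw:
            merged = {**getattr(base, blk), **(raw[blk] or {})}
            raw[blk] = merged
    return RunConfig(**{**{k: getattr(base, k) for k in known}, **raw})


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:12]
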