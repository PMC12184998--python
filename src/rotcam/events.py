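"""Coincidence-event selection: resolution smearing, TDC/ADC cuts, photopeak
fitting and scatterer/absorber ordering.

Events live in a pandas DataFrame with the list-mode columns
``event_id, time_lag_ns, crystal_a, crystal_b, e_a_kev, e_b_kev,
theta_rot_deg`` (see :mod:`rotcam.io`); ordered events gain
``scatterer, absorber, e1_kev, e2_kev, weight``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .transport import HistoryBatch

__all__ = [
    "ResolutionModel",
    "CSI_MEASURED",
    "CAF2_MEASURED",
    "EnergyWindow",
    "smear_deposits",
    "tdc_cut",
    "adc_cut",
    "order_scatterer_absorber",
    "fit_photopeaks",
    "total_energy_spectrum",
    "resolution_for_material",
]

ME_C2 = 511.0
EVENT_COLUMNS = ["event_id", "time_lag_ns", "crystal_a", "crystal_b",
                 "e_a_kev", "e_b_kev", "theta_rot_deg"]


@dataclass(frozen=True)
class ResolutionModel:
    """Energy resolution sigma(E) = a * E**b, keV in / keV out."""

    a: float
    b: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0 or not (0 < self.b < 1):
            raise ValueError("require a > 0 and 0 < b < 1")

    def sigma(self, energy_kev):
        return self.a * np.asarray(energy_kev, dtype=float) ** self.b

    def window(self, center_kev: float, n_sigma: float = 3.0,
               n_sigma_low: float | None = None) -> "EnergyWindow":
        """Photopeak window center +/- n_sigma (asymmetric if n_sigma_low set)."""
        s = float(self.sigma(center_kev))
        lo = center_kev - (n_sigma if n_sigma_low is None else n_sigma_low) * s
        return EnergyWindow(center_kev, lo, center_kev + n_sigma * s)


# measured with a 3.5 cm CsI(Tl) cube + PMT
CSI_MEASURED = ResolutionModel(0.5746, 0.5736, "CsI(Tl) measured")
# measured with a 3.5 cm CaF2(Eu) cube + metal-packaged PMT
CAF2_MEASURED = ResolutionModel(1.001, 0.4963, "CaF2(Eu) measured")


def resolution_for_material(name: str) -> ResolutionModel:
    """CaF2 preset for CaF2 detectors; the CsI preset otherwise (CsI, NaI)."""
    return CAF2_MEASURED if name == "CaF2" else CSI_MEASURED


@dataclass(frozen=True)
class EnergyWindow:
    center: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower < self.center < self.upper):
            raise ValueError("window requires lower < center < upper")


def smear_deposits(
    batch: HistoryBatch,
    model: ResolutionModel,
    threshold_kev: float = 10.0,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Gaussian-smear true deposits and keep exactly-two-crystal candidates.

    Each nonzero deposit E becomes E + N(0, sigma(E)); non-positive smeared
    values are redrawn (keeps the peak unbiased at these energies).  Deposits
    below ``threshold_kev`` are dropped; a candidate survives only if exactly
    two crystals remain.  Simulated events carry ``time_lag_ns = 0``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dep = batch.deposits
    mask = dep > 0
    smeared = np.zeros_like(dep)
    if mask.any():
        e = dep[mask]
        sig = model.sigma(e)
        val = e + rng.normal(0.0, 1.0, e.shape) * sig
        bad = val <= 0
        while bad.any():
            val[bad] = e[bad] + rng.normal(0.0, 1.0, int(bad.sum())) * sig[bad]
            bad = val <= 0
        smeared[mask] = val
    above = smeared >= threshold_kev
    keep = above.sum(axis=1) == 2
    rows = np.flatnonzero(keep)
    idx = np.argsort(~above[rows], axis=1, kind="stable")[:, :2]  # the two hit crystals
    ca, cb = idx[:, 0], idx[:, 1]
    ea = smeared[rows, ca]
    eb = smeared[rows, cb]
    return pd.DataFrame({
        "event_id": rows,
        "time_lag_ns": np.zeros(rows.size),
        "crystal_a": ca.astype(np.int64),
        "crystal_b": cb.astype(np.int64),
        "e_a_kev": ea,
        "e_b_kev": eb,
        "theta_rot_deg": batch.theta_rot[rows],
    })


def tdc_cut(events: pd.DataFrame, window_ns: float = 400.0) -> pd.DataFrame:
    """Keep twofold coincidences with |time lag| <= window (default 400 ns).

    Simulated events have zero lag and always pass; the cut matters for
    imported measurements where accidental coincidences populate the tails.
    """
    return events[events["time_lag_ns"].abs() <= window_ns].reset_index(drop=True)


def adc_cut(events: pd.DataFrame, window: EnergyWindow) -> pd.DataFrame:
    """Keep events whose total energy E1+E2 lies in the closed window."""
    tot = events["e_a_kev"] + events["e_b_kev"]
    return events[(tot >= window.lower) & (tot <= window.upper)].reset_index(drop=True)


# |cos theta| may exceed 1 by rounding for exact-backscatter deposits quoted
# at keV precision; accept within this slack (the angle is clipped downstream)
KINEMATIC_COS_TOL = 1e-3


def _cos_theta(e1, e2):
    # Compton kinematics: cos(theta) = 1 - me c^2 (1/E2 - 1/(E1+E2))
    return 1.0 - ME_C2 * (1.0 / e2 - 1.0 / (e1 + e2))


def order_scatterer_absorber(events: pd.DataFrame, strategy: str = "kinematic") -> pd.DataFrame:
    """Assign scatterer/absorber roles to the two deposits of each event.

    The photopeak total fixes the incident energy, but which crystal saw the
    recoil electron (E1) and which the scattered photon (E2) is ambiguous.

    Strategies:

    * ``kinematic`` (default): keep every assignment with a physical
      scattering angle (|cos theta| <= 1); if both survive each carries
      weight 1/2.  Events with no valid assignment are discarded.
    * ``both``: always keep both assignments at weight 1/2.
    * ``lower_first``: the smaller deposit is the scatterer, weight 1.

    Returns ordered events with columns ``scatterer, absorber, e1_kev,
    e2_kev, theta_rot_deg, weight`` (and ``time_lag_ns`` carried through);
    ``attrs['n_discarded']`` counts kinematically impossible events.
    """
    ea = events["e_a_kev"].to_numpy()
    eb = events["e_b_kev"].to_numpy()
    ca = events["crystal_a"].to_numpy()
    cb = events["crystal_b"].to_numpy()
    rot = events["theta_rot_deg"].to_numpy()
    lag = events["time_lag_ns"].to_numpy()
    eid = events["event_id"].to_numpy()

    if strategy == "lower_first":
        swap = ea > eb
        e1 = np.where(swap, eb, ea)
        e2 = np.where(swap, ea, eb)
        out = pd.DataFrame({
            "event_id": eid,
            "time_lag_ns": lag,
            "scatterer": np.where(swap, cb, ca),
            "absorber": np.where(swap, ca, cb),
            "e1_kev": e1, "e2_kev": e2,
            "theta_rot_deg": rot,
            "weight": np.ones(ea.size),
        })
        out.attrs["n_discarded"] = 0
        return out

    cos_ab = _cos_theta(ea, eb)  # E1 in a, E2 in b
    cos_ba = _cos_theta(eb, ea)
    ok_ab = np.abs(cos_ab) <= 1.0 + KINEMATIC_COS_TOL
    ok_ba = np.abs(cos_ba) <= 1.0 + KINEMATIC_COS_TOL
    if strategy == "both":
        ok_ab = np.ones_like(ok_ab)
        ok_ba = np.ones_like(ok_ba)
    elif strategy != "kinematic":
        raise ValueError(f"unknown ordering strategy {strategy!r}")
    n_valid = ok_ab.astype(int) + ok_ba.astype(int)
    w = np.where(n_valid > 0, 1.0 / np.maximum(n_valid, 1), 0.0)

    parts = []
    for ok, scat, absb, e1, e2 in ((ok_ab, ca, cb, ea, eb), (ok_ba, cb, ca, eb, ea)):
        m = ok & (n_valid > 0)
        parts.append(pd.DataFrame({
            "event_id": eid[m],
            "time_lag_ns": lag[m],
            "scatterer": scat[m],
            "absorber": absb[m],
            "e1_kev": e1[m], "e2_kev": e2[m],
            "theta_rot_deg": rot[m],
            "weight": w[m],
        }))
    out = pd.concat(parts, ignore_index=True).sort_values(
        ["event_id", "scatterer"], kind="stable").reset_index(drop=True)
    out.attrs["n_discarded"] = int((n_valid == 0).sum())
    return out


def total_energy_spectrum(events: pd.DataFrame, bin_kev: float = 2.0,
                          e_min: float = 60.0, e_max: float = 260.0):
    """Histogram of E1+E2; returns (bin_centers, counts)."""
    tot = (events["e_a_kev"] + events["e_b_kev"]).to_numpy()
    edges = np.arange(e_min, e_max + bin_kev / 2, bin_kev)
    counts, _ = np.histogram(tot, bins=edges)
    return 0.5 * (edges[:-1] + edges[1:]), counts


def _double_gauss_exp(e, p0, p1, p2, p3, p4, p5):
    return (p0 * np.exp(-((e - 113.0) ** 2) / (2 * p1**2))
            + p2 * np.exp(-((e - 141.0) ** 2) / (2 * p3**2))
            + np.exp(p4 * e + p5))


def fit_photopeaks(bin_centers, counts, peaks=(113.0, 141.0)):
    """Fit the 113/141 keV photopeak region with two Gaussians + exponential.

    Model: ``p0 exp(-(E-113)^2/2 p1^2) + p2 exp(-(E-141)^2/2 p3^2)
    + exp(p4 E + p5)`` with the peak centers fixed.  Returns a dict with the
    parameters, their standard errors, and the asymmetric 141 keV selection
    window [141 - sigma, 141 + 2 sigma] (sigma = p3) that limits leakage from
    the 113 keV peak.
    """
    if tuple(peaks) != (113.0, 141.0):
        raise ValueError("the spectral model fixes peak centers at 113 and 141 keV")
    e = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)
    # initial values: local amplitudes and a crude continuum slope
    amp113 = max(y[np.abs(e - 113).argmin()], 1.0)
    amp141 = max(y[np.abs(e - 141).argmin()], 1.0)
    tail = max(float(np.median(y[-10:])), 0.5)
    p0 = [amp113, 9.0, amp141, 10.0, -0.01, math.log(tail) + 0.01 * e[-1]]
    sigma_y = np.sqrt(np.maximum(y, 1.0))
    try:
        popt, pcov = curve_fit(_double_gauss_exp, e, y, p0=p0, sigma=sigma_y,
                               absolute_sigma=True, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"photopeak fit did not converge (initial values {p0})") from err
    perr = np.sqrt(np.diag(pcov))
    popt[1] = abs(popt[1])
    popt[3] = abs(popt[3])
    s141 = popt[3]
    window_141 = EnergyWindow(141.0, 141.0 - s141, 141.0 + 2 * s141)
    return {
        "params": popt,
        "errors": perr,
        "window_141": window_141,
        "sigma_113": popt[1],
        "sigma_141": s141,
    }
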