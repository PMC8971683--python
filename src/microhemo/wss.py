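"""Two-regime wall shear stress (WSS) statistics.

A vessel's endothelium is split per frame into the part adjacent to a red
cell and the plasma-only remainder. Plasma WSS follows Poiseuille flow,
sigma_p = 4*mu*v/r; next to a cell the occlusive resistance increment adds
pi*r^3*v*alpha_c/(2*l_cell). Stresses are computed in SI (Pa) and reported
in dyne/cm^2 (1 Pa = 10 dyne/cm^2); velocities enter in cm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DYN_CM2_PER_PA = 10.0
UM = 1e-6

__all__ = [
    "WSSParams", "WSSDecomposition", "PeakStressResult",
    "plasma_wss", "cell_wss", "occupied_fraction",
    "build_wss_decomposition", "plasma_threshold", "peak_stress_portion",
    "NoSamplesError",
]


class NoSamplesError(ValueError):
    """An empty sample pool where at least one value is required."""


@dataclass(frozen=True)
class WSSParams:
    mu: float = 1.0e-3            # Pa.s
    radius_um: float = 3.0
    cell_length_um: float = 6.0
    alpha_c: float = 0.0          # Pa.s/m^3 per cell

    def __post_init__(self):
        if not (self.mu > 0 and self.radius_um > 0 and self.cell_length_um > 0):
            raise ValueError("mu, radius and cell length must be positive")
        if self.alpha_c < 0:
            raise ValueError("alpha_c must be >= 0")


def plasma_wss(params: WSSParams, v_cms: float) -> float:
    """Plasma-regime WSS, dyne/cm^2, for median cell speed ``v_cms`` (cm/s)."""
    if v_cms < 0:
        raise ValueError("speed must be >= 0")
    v = v_cms / 100.0                       # m/s
    r = params.radius_um * UM
    sigma_pa = 4.0 * params.mu * v / r
    return sigma_pa * DYN_CM2_PER_PA


def cell_wss(params: WSSParams, v_cms: float) -> float:
    """Cell-adjacent WSS, dyne/cm^2: plasma term plus the occlusive term."""
    if v_cms < 0:
        raise ValueError("speed must be >= 0")
    v = v_cms / 100.0
    r = params.radius_um * UM
    l_cell = params.cell_length_um * UM
    sigma_pa = (4.0 * params.mu * v / r
                + math.pi * r ** 3 * v * params.alpha_c / (2.0 * l_cell))
    return sigma_pa * DYN_CM2_PER_PA


def occupied_fraction(cells, cell_length_um: float, vessel_length_um: float) -> float:
    """Fraction of the endothelium adjacent to cells in one frame.

    ``cells`` is either an integer count (windows assumed disjoint, capped
    at 1) or an iterable of cell-centre arclengths, in which case the
    windows [s - l/2, s + l/2], clipped to the vessel, are merged by
    interval union before measuring.
    """
    if not vessel_length_um > 0:
        raise ValueError("vessel length must be positive")
    if isinstance(cells, (int, np.integer)):
        if cells < 0:
            raise ValueError("cell count must be >= 0")
        return min(1.0, cells * cell_length_um / vessel_length_um)
    centers = np.asarray(list(cells), dtype=float)
    if centers.size == 0:
        return 0.0
    half = cell_length_um / 2.0
    lo = np.clip(centers - half, 0.0, vessel_length_um)
    hi = np.clip(centers + half, 0.0, vessel_length_um)
    order = np.argsort(lo)
    covered = 0.0
    cur_lo, cur_hi = lo[order[0]], hi[order[0]]
    for i in order[1:]:
        if lo[i] <= cur_hi:
            cur_hi = max(cur_hi, hi[i])
        else:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo[i], hi[i]
    covered += cur_hi - cur_lo
    return covered / vessel_length_um


@dataclass
class WSSDecomposition:
    vessel_id: str
    sigma_p_dyncm2: np.ndarray        # per frame
    sigma_cell_dyncm2: np.ndarray     # per frame
    occupied_fraction: np.ndarray     # per frame, in [0, 1]

    def __post_init__(self):
        n = len(self.sigma_p_dyncm2)
        if not (len(self.sigma_cell_dyncm2) == n == len(self.occupied_fraction)):
            raise ValueError("per-frame arrays must share length")
        if np.any(self.occupied_fraction < 0) or np.any(self.occupied_fraction > 1):
            raise ValueError("occupied_fraction must lie in [0, 1]")


@dataclass
class PeakStressResult:
    threshold_dyncm2: float
    portion: float                    # fraction of endothelium-time above threshold

    def __post_init__(self):
        if not 0.0 <= self.portion <= 1.0:
            raise ValueError("portion must lie in [0, 1]")
        if self.threshold_dyncm2 < 0:
            raise ValueError("threshold must be >= 0")


def build_wss_decomposition(frames, vessel_length_um: float, v_cms: float,
                            params: WSSParams, vessel_id: str = "vessel") -> WSSDecomposition:
    """Per-frame decomposition from cell occupancy.

    ``frames`` is a sequence with one entry per frame: either an integer
    cell count or an array of cell-centre arclengths (um). The same median
    speed ``v_cms`` drives both regimes.
    """
    occ = np.array([occupied_fraction(f, params.cell_length_um, vessel_length_um)
                    for f in frames])
    n = len(occ)
    sp = np.full(n, plasma_wss(params, v_cms))
    sc = np.full(n, cell_wss(params, v_cms))
    return WSSDecomposition(vessel_id, sp, sc, occ)


def plasma_threshold(samples, q: float = 0.975) -> float:
    """Quantile of pooled plasma WSS samples (linear interpolation).

    The pool spans all intersegmental vessels and frames; the default 0.975
    quantile is the activation threshold.
    """
    arr = np.asarray(list(samples), dtype=float).ravel()
    if arr.size == 0:
        raise NoSamplesError("empty plasma stress pool")
    return float(np.quantile(arr, q))


def peak_stress_portion(decomp: WSSDecomposition, threshold_dyncm2: float) -> float:
    """Fraction of endothelium-time with WSS above the threshold.

    Per frame the occupied fraction contributes when the cell-adjacent
    stress exceeds the threshold and the remainder contributes when the
    plasma stress does; the portion is the mean over frames.
    """
    if threshold_dyncm2 < 0:
        raise ValueError("threshold must be >= 0")
    occ = decomp.occupied_fraction
    above_cell = decomp.sigma_cell_dyncm2 > threshold_dyncm2
    above_plasma = decomp.sigma_p_dyncm2 > threshold_dyncm2
    per_frame = occ * above_cell + (1.0 - occ) * above_plasma
    return float(per_frame.mean())
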