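"""Batch colocalization: multilevel Otsu masks, overlap, component-area filter.

Thresholds maximize the between-class variance of the intensity histogram;
for up to four classes the optimum is found by exhaustive search over bin
combinations. Masks are binary (foreground 1, background 0); the overlap is
a pixel-wise conjunction and connected components outside the configured
pixel-count window (default 20-500 px) are removed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "BinaryMask", "ColocResult",
    "otsu_thresholds", "binarize", "overlap_mask", "filter_components",
    "DegenerateHistogramError",
]


class DegenerateHistogramError(ValueError):
    """The image histogram cannot support the requested number of classes."""


@dataclass
class BinaryMask:
    mask: np.ndarray                 # bool
    pixel_size_um: float = 1.136

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def foreground_px(self) -> int:
        return int(self.mask.sum())

    @property
    def foreground_um2(self) -> float:
        return self.foreground_px * self.pixel_size_um ** 2


@dataclass
class ColocResult:
    components: pd.DataFrame         # component_id, pixel_count, area_um2
    total_px: int
    total_um2: float


def _histogram(image: np.ndarray, nbins: int | None):
    img = np.asarray(image)
    if np.issubdtype(img.dtype, np.integer):
        vmax = int(img.max())
        if nbins is None:
            nbins = 65536 if img.dtype.itemsize > 1 else 256
        nbins = min(nbins, max(vmax + 1, 2))
        values = np.arange(nbins, dtype=float)
        counts = np.bincount(img.ravel().astype(np.int64), minlength=nbins)[:nbins]
    else:
        if nbins is None:
            nbins = 256
        counts, edges = np.histogram(img.ravel(), bins=nbins)
        values = 0.5 * (edges[:-1] + edges[1:])
    return values, counts.astype(float)


def otsu_thresholds(image: np.ndarray, n_classes: int = 2,
                    nbins: int | None = None) -> np.ndarray:
    """Multilevel Otsu thresholds, ascending.

    Maximizes the between-class variance (equivalently sum of
    weight * class-mean^2) over all combinations of n_classes-1 cut bins;
    exhaustive for n_classes <= 4 so the optimum is guaranteed. A threshold
    value t assigns pixels >= t to the upper class. Multilevel search on
    >8-bit data is carried out on a 256-bin rebinning of the value range.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_classes > 4:
        raise ValueError("exhaustive search supports at most 4 classes")
    img = np.asarray(image)
    if np.unique(img).size < n_classes:
        raise DegenerateHistogramError(
            f"image has fewer than {n_classes} distinct values")
    if n_classes > 2 and np.issubdtype(img.dtype, np.integer) and img.dtype.itemsize > 1:
        nbins = 256 if nbins is None else nbins

    values, counts = _histogram(img, nbins)
    p = counts / counts.sum()
    cum_w = np.concatenate([[0.0], np.cumsum(p)])
    cum_s = np.concatenate([[0.0], np.cumsum(p * values)])

    occupied = np.flatnonzero(counts)
    # candidate cut positions: class boundaries directly above occupied bins
    cand = np.unique(occupied + 1)
    cand = cand[cand < len(values)]
    if cand.size < n_classes - 1:
        raise DegenerateHistogramError("not enough occupied bins for the cut count")

    def objective(cuts: np.ndarray) -> np.ndarray:
        """Sum over classes of S^2/W for cut arrays of shape (m, k-1)."""
        bounds = np.concatenate(
            [np.zeros((cuts.shape[0], 1), dtype=int), cuts,
             np.full((cuts.shape[0], 1), len(values), dtype=int)], axis=1)
        total = np.zeros(cuts.shape[0])
        for k in range(bounds.shape[1] - 1):
            w = cum_w[bounds[:, k + 1]] - cum_w[bounds[:, k]]
            s = cum_s[bounds[:, k + 1]] - cum_s[bounds[:, k]]
            with np.errstate(divide="ignore", invalid="ignore"):
                total += np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
        return total

    if n_classes == 2:
        cuts = cand[:, None]
    else:
        cuts = np.array(list(itertools.combinations(cand, n_classes - 1)), dtype=int)
    best = cuts[int(np.argmax(objective(cuts)))]
    return values[np.sort(best)]


def binarize(image: np.ndarray, thresholds, threshold_index: int = -1,
             pixel_size_um: float = 1.136) -> BinaryMask:
    """Foreground = pixels >= thresholds[threshold_index]."""
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    try:
        t = thresholds[threshold_index]
    except IndexError as exc:
        raise ValueError(
            f"threshold_index {threshold_index} out of range for "
            f"{thresholds.size} thresholds") from exc
    return BinaryMask(np.asarray(image) >= t, pixel_size_um)


def overlap_mask(mask_a: BinaryMask, mask_b: BinaryMask) -> BinaryMask:
    """Pixel-wise conjunction of two masks of identical shape."""
    if mask_a.mask.shape != mask_b.mask.shape:
        raise ValueError(f"mask shapes differ: {mask_a.mask.shape} "
                         f"vs {mask_b.mask.shape}")
    return BinaryMask(mask_a.mask & mask_b.mask, mask_a.pixel_size_um)


def filter_components(mask: BinaryMask, min_px: int = 20, max_px: int = 500,
                      connectivity: int = 8) -> tuple:
    """Keep connected components whose pixel count lies in [min_px, max_px].

    Bounds are inclusive and defined on pixel counts; areas in um^2 are
    reported alongside. Connectivity is 4 or 8 (default 8).
    """
    if min_px > max_px:
        raise ValueError("min_px must not exceed max_px")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    counts = np.bincount(labels.ravel())
    keep_ids = [i for i in range(1, counts.size)
                if min_px <= counts[i] <= max_px]
    kept = np.isin(labels, keep_ids)
    px2 = mask.pixel_size_um ** 2
    comp = pd.DataFrame(
        [(i, int(counts[i]), counts[i] * px2) for i in keep_ids],
        columns=["component_id", "pixel_count", "area_um2"])
    total = int(comp["pixel_count"].sum()) if len(comp) else 0
    return BinaryMask(kept, mask.pixel_size_um), ColocResult(comp, total, total * px2)
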