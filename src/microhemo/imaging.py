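"""Ground-truthed synthetic fluorescence data.

Renders time-lapse movies of point cells advected along vessel centerlines
(isotropic Gaussian point-spread blobs plus configurable noise) and
two-channel component images with exactly known overlap, so the tracking
and colocalization stages can be tested without any acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry

__all__ = [
    "ImagingConfig", "MovieStack", "GroundTruth", "ChannelPairTruth",
    "render_movie", "render_coloc_pair", "make_linear_trajectories",
    "PackingError",
]


class PackingError(RuntimeError):
    """Requested components cannot be placed without touching."""


@dataclass(frozen=True)
class ImagingConfig:
    """Camera/optics surrogate.

    ``noise_model`` is ``None``/"none", ("gaussian", sigma) for additive
    read noise, or ("poisson", scale) for shot noise on ``scale`` photons
    per intensity unit. The default pixel size corresponds to a 1.29 um^2
    pixel area.
    """

    pixel_size_um: float = 1.136
    frame_rate_fps: float = 20.0
    psf_sigma_um: float = 1.0
    cell_peak_intensity: float = 200.0
    background_level: float = 10.0
    noise_model: object = None
    bit_depth: int = 8
    field_shape: tuple = (64, 512)        # (rows, cols)

    def __post_init__(self):
        if min(self.pixel_size_um, self.frame_rate_fps, self.psf_sigma_um) <= 0:
            raise ValueError("pixel size, frame rate and PSF sigma must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class MovieStack:
    frames: np.ndarray                    # (T, H, W), dtype per bit depth
    config: ImagingConfig


@dataclass
class GroundTruth:
    records: pd.DataFrame                 # frame, cell_id, x_um, y_um, edge_id,
                                          # arclength_um, in_field
    centerlines: dict = field(default_factory=dict)


@dataclass
class ChannelPairTruth:
    channel_a: np.ndarray
    channel_b: np.ndarray
    mask_a: np.ndarray                    # true foreground, bool
    mask_b: np.ndarray
    overlap: np.ndarray                   # true overlap mask, bool
    areas_a: list                         # per-component pixel counts
    areas_b: list
    overlap_areas: list


def _apply_noise(img: np.ndarray, noise_model, rng: np.random.Generator) -> np.ndarray:
    if noise_model is None or noise_model == "none":
        return img
    kind, value = noise_model
    if kind == "gaussian":
        return img + rng.normal(0.0, value, size=img.shape)
    if kind == "poisson":
        return rng.poisson(np.clip(img, 0, None) * value).astype(float) / value
    raise ValueError(f"unknown noise model {noise_model!r}")


def _quantize(img: np.ndarray, config: ImagingConfig) -> np.ndarray:
    return np.clip(np.rint(img), 0, config.max_value).astype(config.dtype)


def _stamp_gaussian(frame: np.ndarray, row: float, col: float,
                    sigma_px: float, amplitude: float) -> None:
    """Add an isotropic Gaussian blob in place, clipped at the field edge."""
    h, w = frame.shape
    half = int(np.ceil(4 * sigma_px))
    r0, r1 = int(np.floor(row)) - half, int(np.floor(row)) + half + 1
    c0, c1 = int(np.floor(col)) - half, int(np.floor(col)) + half + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c)[:, None] - row
    cc = np.arange(c0c, c1c)[None, :] - col
    frame[r0c:r1c, c0c:c1c] += amplitude * np.exp(-(rr ** 2 + cc ** 2)
                                                  / (2.0 * sigma_px ** 2))


def render_movie(trajectories: pd.DataFrame, centerlines: dict,
                 config: ImagingConfig, seed: int = 0) -> tuple:
    """Render a (MovieStack, GroundTruth) pair from cell trajectories.

    ``trajectories`` needs columns time_s, cell_id, edge_id, arclength_um
    (the output of the transport simulator); ``centerlines`` maps edge ids
    to (N, 2) polylines in um. The trajectory time base is resampled to the
    frame clock by nearest-sample lookup. Cells outside the field are
    rendered clipped but kept in the truth table with ``in_field`` False.
    """
    required = {"time_s", "cell_id", "edge_id", "arclength_um"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectories missing columns: {sorted(missing)}")
    for eid in trajectories["edge_id"].unique():
        if eid not in centerlines:
            raise ValueError(f"no centerline for edge {eid!r}")
    rng = np.random.default_rng(seed)
    h, w = config.field_shape
    sigma_px = config.psf_sigma_um / config.pixel_size_um

    t_end = float(trajectories["time_s"].max()) if len(trajectories) else 0.0
    n_frames = max(1, int(np.floor(t_end * config.frame_rate_fps)) + 1)
    frame_times = np.arange(n_frames) / config.frame_rate_fps

    times = np.sort(trajectories["time_s"].unique()) if len(trajectories) else np.array([])
    frames = np.empty((n_frames, h, w), dtype=config.dtype)
    truth_rows = []
    by_time = dict(tuple(trajectories.groupby("time_s"))) if len(trajectories) else {}

    for f, t in enumerate(frame_times):
        img = np.full((h, w), float(config.background_level))
        if times.size:
            k = int(np.argmin(np.abs(times - t)))
            snap = by_time[times[k]]
            for rec in snap.itertuples(index=False):
                verts = np.asarray(centerlines[rec.edge_id], dtype=float)
                x, y = geometry.point_at(verts, float(rec.arclength_um))
                col = x / config.pixel_size_um
                row = y / config.pixel_size_um
                _stamp_gaussian(img, row, col, sigma_px, config.cell_peak_intensity)
                in_field = (-0.5 <= row <= h - 0.5) and (-0.5 <= col <= w - 0.5)
                truth_rows.append((f, int(rec.cell_id), float(x), float(y),
                                   rec.edge_id, float(rec.arclength_um), in_field))
        img = _apply_noise(img, config.noise_model, rng)
        frames[f] = _quantize(img, config)

    records = pd.DataFrame(truth_rows, columns=["frame", "cell_id", "x_um", "y_um",
                                                "edge_id", "arclength_um", "in_field"])
    return MovieStack(frames, config), GroundTruth(records, dict(centerlines))


def make_linear_trajectories(n_cells: int, speed_cms: float, duration_s: float,
                             frame_rate_fps: float, start_um=None,
                             spacing_um: float = 12.0,
                             edge_id: str = "v0") -> pd.DataFrame:
    """Constant-speed cells on one straight vessel, sampled on the frame clock.

    Convenience generator for round-trip tests: cell i starts at
    ``start_um[i]`` (default ``10 + i*spacing_um``) and moves at
    ``speed_cms`` (signed) along the edge.
    """
    if start_um is None:
        start_um = 10.0 + spacing_um * np.arange(n_cells)
    start_um = np.asarray(start_um, dtype=float)
    n_frames = int(np.floor(duration_s * frame_rate_fps)) + 1
    t = np.arange(n_frames) / frame_rate_fps
    speed_ums = speed_cms * 1e4
    rows = []
    for i in range(n_cells):
        for tf in t:
            rows.append((float(tf), i, edge_id, float(start_um[i] + speed_ums * tf)))
    return pd.DataFrame(rows, columns=["time_s", "cell_id", "edge_id", "arclength_um"])


def render_coloc_pair(n_components: int = 5, overlap_fraction: float = 0.5,
                      component_px_range: tuple = (100, 100),
                      noise_model=None, seed: int = 0,
                      field_shape: tuple = (128, 128),
                      foreground_level: float = 200.0,
                      background_level: float = 10.0,
                      bit_depth: int = 8) -> ChannelPairTruth:
    """Two-channel fixture with exactly known component masks and overlap.

    Each component is a rectangle; channel B repeats channel A's rectangle
    shifted so the overlapping area is ``round(overlap_fraction * width)``
    columns wide. Components are laid out on a margin grid so neither
    channel's components touch. Deterministic given ``seed``.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    lo, hi = component_px_range
    if lo > hi or lo < 1:
        raise ValueError("invalid component_px_range")
    rng = np.random.default_rng(seed)
    h, w = field_shape
    mask_a = np.zeros((h, w), dtype=bool)
    mask_b = np.zeros((h, w), dtype=bool)
    areas_a, areas_b, overlap_areas = [], [], []

    placed = []          # bounding boxes (r0, c0, r1, c1) incl. margin
    margin = 2
    attempts = 0
    for _ in range(n_components):
        target = int(rng.integers(lo, hi + 1))
        ch = max(1, int(np.floor(np.sqrt(target))))
        cw = max(1, target // ch)
        shift = int(round((1.0 - overlap_fraction) * cw))
        full_w = cw + shift
        while True:
            attempts += 1
            if attempts > 200 * n_components:
                raise PackingError("could not place components without contact")
            r0 = int(rng.integers(margin, max(margin + 1, h - ch - margin)))
            c0 = int(rng.integers(margin, max(margin + 1, w - full_w - margin)))
            box = (r0 - margin, c0 - margin, r0 + ch + margin, c0 + full_w + margin)
            if box[2] > h or box[3] > w:
                continue
            if all(box[2] <= b[0] or b[2] <= box[0] or box[3] <= b[1] or b[3] <= box[1]
                   for b in placed):
                placed.append(box)
                break
        mask_a[r0:r0 + ch, c0:c0 + cw] = True
        mask_b[r0:r0 + ch, c0 + shift:c0 + shift + cw] = True
        areas_a.append(ch * cw)
        areas_b.append(ch * cw)
        overlap_areas.append(ch * max(0, cw - shift))

    overlap = mask_a & mask_b
    max_value = (1 << bit_depth) - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    imgs = []
    for mask in (mask_a, mask_b):
        img = np.full((h, w), float(background_level))
        img[mask] = foreground_level
        img = _apply_noise(img, noise_model, rng)
        imgs.append(np.clip(np.rint(img), 0, max_value).astype(dtype))
    return ChannelPairTruth(imgs[0], imgs[1], mask_a, mask_b, overlap,
                            areas_a, areas_b, overlap_areas)
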