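"""Polyline geometry helpers shared by the tracking and imaging modules.

All coordinates are in micrometres. A polyline is an (N, 2) float array of
vertices; arclength is measured cumulatively along its segments.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cumulative_arclength", "polyline_length", "point_at", "tangent_at"]


def cumulative_arclength(vertices: np.ndarray) -> np.ndarray:
    """Cumulative arclength table for a polyline, starting at 0."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("polyline needs at least two 2-D vertices")
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_length(vertices: np.ndarray) -> float:
    return float(cumulative_arclength(vertices)[-1])


def point_at(vertices: np.ndarray, s: float | np.ndarray,
             cumlen: np.ndarray | None = None) -> np.ndarray:
    """Point(s) on the polyline at arclength ``s`` (clipped to [0, length])."""
    v = np.asarray(vertices, dtype=float)
    cl = cumulative_arclength(v) if cumlen is None else cumlen
    s1 = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cl[-1])
    idx = np.clip(np.searchsorted(cl, s1, side="right") - 1, 0, len(cl) - 2)
    seg_len = cl[idx + 1] - cl[idx]
    frac = np.where(seg_len > 0, (s1 - cl[idx]) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
    pts = v[idx] + frac[:, None] * (v[idx + 1] - v[idx])
    return pts[0] if np.ndim(np.asarray(s)) == 0 else pts


def tangent_at(vertices: np.ndarray, s: float | np.ndarray,
               cumlen: np.ndarray | None = None) -> np.ndarray:
    """Unit tangent(s) of the polyline at arclength ``s``."""
    v = np.asarray(vertices, dtype=float)
    cl = cumulative_arclength(v) if cumlen is None else cumlen
    s1 = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cl[-1])
    idx = np.clip(np.searchsorted(cl, s1, side="right") - 1, 0, len(cl) - 2)
    d = v[idx + 1] - v[idx]
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    t = d / np.where(norm > 0, norm, 1.0)
    return t[0] if np.ndim(s) == 0 else t
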