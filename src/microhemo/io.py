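"""Readers/writers for the pipeline's on-disk formats.

Movies are multi-page TIFF with a JSON sidecar (pixel size, frame rate,
seed, config echo); tables are comma-separated UTF-8 CSV with unit-suffixed
column names; networks are versioned JSON. Every command writes a manifest
with a config echo and SHA-256 checksums of its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .imaging import MovieStack
from .tracking import VesselTrace

__all__ = [
    "SchemaError", "write_movie", "read_movie", "write_centerlines",
    "read_centerlines", "read_table", "write_manifest", "sha256_file",
]


class SchemaError(ValueError):
    """An input file is missing required keys or columns."""


def write_movie(path, stack: MovieStack, seed: int | None = None) -> Path:
    """Write a TIFF stack plus its ``<stem>.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    cfg = dataclasses.asdict(stack.config)
    cfg["noise_model"] = (list(cfg["noise_model"])
                          if isinstance(cfg["noise_model"], tuple) else cfg["noise_model"])
    cfg["field_shape"] = list(cfg["field_shape"])
    sidecar = {
        "pixel_size_um": stack.config.pixel_size_um,
        "frame_rate_fps": stack.config.frame_rate_fps,
        "seed": seed,
        "config": cfg,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_movie(path) -> tuple:
    """Read a TIFF stack and its sidecar; returns (frames, sidecar dict)."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("pixel_size_um", "frame_rate_fps"):
        if key not in sidecar or sidecar[key] is None:
            raise SchemaError(f"sidecar missing required key: {key}")
    return frames, sidecar


def write_centerlines(path, traces) -> Path:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(np.asarray(t.vertices, dtype=float)):
            rows.append((t.vessel_id, i, x, y))
    pd.DataFrame(rows, columns=["vessel_id", "vertex_index", "x_um", "y_um"]) \
        .to_csv(path, index=False)
    return Path(path)


def read_centerlines(path) -> list:
    df = read_table(path, required=("vessel_id", "vertex_index", "x_um", "y_um"))
    traces = []
    for vid, grp in df.groupby("vessel_id", sort=True):
        grp = grp.sort_values("vertex_index")
        traces.append(VesselTrace(str(vid), grp[["x_um", "y_um"]].to_numpy()))
    return traces


def read_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {missing}")
    return df


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, command: str, config: dict, seed: int | None,
                   outputs) -> Path:
    outdir = Path(outdir)
    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed,
        "config": config,
        "outputs": {Path(p).name: sha256_file(p) for p in outputs},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
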