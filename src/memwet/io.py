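"""Readers and writers for the pipeline's file formats.

Hyperspectral stacks are multi-page TIFFs (one page per spectral channel)
with a YAML/JSON sidecar holding the acquisition metadata; contour sets and
drift tracks are plain CSV tables.  All tabular output goes through pandas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .electrokinetics import DriftTrack
from .phasor import SpectrumStack
from .wetting import ContourSet

__all__ = [
    "StackMeta",
    "read_stack",
    "write_stack",
    "read_contours",
    "write_contours",
    "read_tracks",
    "write_tracks",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class StackMeta:
    """Spectral acquisition metadata of a hyperspectral TIFF."""

    lambda_min: float = 416.0
    lambda_max: float = 728.0
    n_channels: int = 32

    @property
    def bandwidth(self) -> float:
        """Width of one spectral channel in nm."""
        return (self.lambda_max - self.lambda_min) / self.n_channels

    def channel_centers(self) -> np.ndarray:
        return self.lambda_min + self.bandwidth * (np.arange(self.n_channels) + 0.5)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML configuration file (JSON is a subset of YAML)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def dump_config(data: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_stack(tiff_path: str | Path, meta_path: str | Path | None = None) -> SpectrumStack:
    """Read a multi-page spectral TIFF plus its metadata sidecar.

    Pages (or the leading axis) are spectral channels.  The sidecar must
    define lambda_min, lambda_max and n_channels; by default it is looked up
    next to the TIFF as ``<stem>.meta.yaml``.
    """
    tiff_path = Path(tiff_path)
    if meta_path is None:
        meta_path = tiff_path.with_suffix("").with_suffix(".meta.yaml")
    raw = load_config(meta_path)
    meta = StackMeta(lambda_min=float(raw["lambda_min"]), lambda_max=float(raw["lambda_max"]),
                     n_channels=int(raw["n_channels"]))
    arr = tifffile.imread(tiff_path)
    if arr.ndim != 3:
        raise ValueError("expected a (channels, rows, cols) TIFF stack")
    if arr.shape[0] != meta.n_channels:
        raise ValueError(f"TIFF has {arr.shape[0]} channels, metadata says {meta.n_channels}")
    return SpectrumStack(intensities=np.moveaxis(arr, 0, 2).astype(float),
                         wavelengths=meta.channel_centers(),
                         lambda_min=meta.lambda_min, lambda_max=meta.lambda_max)


def write_stack(stack: SpectrumStack, tiff_path: str | Path,
                meta_path: str | Path | None = None) -> None:
    """Write a stack as channel-paged TIFF plus YAML metadata sidecar."""
    tiff_path = Path(tiff_path)
    if meta_path is None:
        meta_path = tiff_path.with_suffix("").with_suffix(".meta.yaml")
    tifffile.imwrite(tiff_path, np.moveaxis(stack.intensities, 2, 0).astype(np.float32))
    dump_config({"lambda_min": float(stack.lambda_min), "lambda_max": float(stack.lambda_max),
                 "n_channels": int(stack.wavelengths.size)}, meta_path)


def write_contours(contour_sets: list[ContourSet], path: str | Path) -> None:
    """Write contour sets to CSV with columns x, y, arc_label, image_id."""
    frames = []
    for cs in contour_sets:
        for label, pts in (("ie", cs.arc_ie), ("ic", cs.arc_ic), ("ce", cs.arc_ce)):
            frames.append(pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1],
                                        "arc_label": label, "image_id": cs.image_id}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_contours(path: str | Path, pixel_size: float = 1.0) -> dict[str, ContourSet]:
    """Read a contour CSV into one ContourSet per image_id."""
    df = pd.read_csv(path)
    required = {"x", "y", "arc_label", "image_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"contour CSV must have columns {sorted(required)}")
    out: dict[str, ContourSet] = {}
    for image_id, grp in df.groupby("image_id", sort=False):
        arcs = {}
        for label in ("ie", "ic", "ce"):
            sel = grp[grp["arc_label"] == label]
            if len(sel) < 3:
                raise ValueError(f"image {image_id}: arc '{label}' has <3 points")
            arcs[label] = sel[["x", "y"]].to_numpy(dtype=float)
        out[str(image_id)] = ContourSet(arc_ie=arcs["ie"], arc_ic=arcs["ic"],
                                        arc_ce=arcs["ce"], pixel_size=pixel_size,
                                        image_id=str(image_id))
    return out


def write_tracks(tracks: list[DriftTrack], path: str | Path) -> None:
    """Write drift tracks to CSV with columns t, x, y, track_id."""
    frames = [pd.DataFrame({"t": tr.times, "x": tr.positions[:, 0],
                            "y": tr.positions[:, 1], "track_id": tr.track_id})
              for tr in tracks]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path: str | Path, field_magnitude: float,
                field_axis: tuple[float, float] = (1.0, 0.0)) -> list[DriftTrack]:
    """Read drift tracks from CSV; field parameters come from the caller's config."""
    df = pd.read_csv(path)
    required = {"t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError("track CSV must have columns t, x, y (and optionally track_id)")
    if "track_id" not in df.columns:
        df = df.assign(track_id="track0")
    tracks = []
    for track_id, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("t")
        tracks.append(DriftTrack(times=grp["t"].to_numpy(dtype=float),
                                 positions=grp[["x", "y"]].to_numpy(dtype=float),
                                 field_magnitude=field_magnitude,
                                 field_axis=field_axis, track_id=str(track_id)))
    return tracks
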