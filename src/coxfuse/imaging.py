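"""Histopathology image front-end.

Tiles a tumor-region RGB image into non-overlapping fixed-size squares,
scores each tile by its summed red+green+blue "density", keeps the top-k
densest tiles, rescales channels against a reference image so all images
share channel means, and collapses per-tile feature tables to a
per-patient median vector.

Note on "density": summed RGB literally favors BRIGHT tiles, which on
H&E slides are background-heavy (tissue is darker than background). The
literal sum is the default; ``density_mode="inverted-sum"`` scores
``sum(3*255 - (r+g+b))`` instead, favoring tissue-dense tiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TileScore", "ChannelScale", "tile_image", "select_top_tiles",
           "compute_channel_scale", "apply_channel_scale",
           "aggregate_patient_features", "extract_tile"]


@dataclass(frozen=True)
class TileScore:
    """One tile: 0-based top-left pixel origin and its RGB-sum density."""

    row: int
    col: int
    density: float


@dataclass(frozen=True)
class ChannelScale:
    """Per-channel multiplicative factors: reference mean / image mean."""

    r: float
    g: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


def _check_rgb(image) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    return image


def tile_image(image, tile_size: int = 1000,
               density_mode: str = "sum") -> list:
    """Score all full non-overlapping tiles of an image.

    Partial tiles at the right/bottom margins are discarded, giving
    exactly ``floor(W/ts) * floor(H/ts)`` tiles in row-major order.
    """
    image = _check_rgb(image)
    H, W = image.shape[:2]
    if H < tile_size or W < tile_size:
        raise ValueError(
            f"image {W}x{H} is smaller than one {tile_size}x{tile_size} tile"
        )
    if density_mode not in ("sum", "inverted-sum"):
        raise ValueError("density_mode must be 'sum' or 'inverted-sum'")
    arr = image.astype(np.float64)
    if density_mode == "inverted-sum":
        arr = 255.0 - arr
    scores = []
    for r in range(0, H - tile_size + 1, tile_size):
        for c in range(0, W - tile_size + 1, tile_size):
            density = float(arr[r:r + tile_size, c:c + tile_size].sum())
            scores.append(TileScore(row=r, col=c, density=density))
    return scores


def select_top_tiles(scores, k: int = 10) -> list:
    """The k densest tiles, descending; ties broken by (row, col).

    If fewer than k tiles exist, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = list(scores)
    if not scores:
        raise ValueError("empty tile list")
    ordered = sorted(scores, key=lambda t: (-t.density, t.row, t.col))
    if len(ordered) < k:
        warnings.warn(
            f"only {len(ordered)} tiles available, fewer than requested k={k}"
        )
        return ordered
    return ordered[:k]


def extract_tile(image, tile: TileScore, tile_size: int = 1000) -> np.ndarray:
    """Crop the pixels of a scored tile."""
    image = _check_rgb(image)
    return image[tile.row:tile.row + tile_size, tile.col:tile.col + tile_size]


def compute_channel_scale(image, reference) -> ChannelScale:
    """Scaling factors aligning an image's channel means to a reference's."""
    image = _check_rgb(image)
    reference = _check_rgb(reference)
    img_means = image.reshape(-1, 3).mean(axis=0, dtype=np.float64)
    ref_means = reference.reshape(-1, 3).mean(axis=0, dtype=np.float64)
    if np.any(img_means == 0):
        raise ValueError("zero channel mean in image: scale undefined")
    s = ref_means / img_means
    return ChannelScale(r=float(s[0]), g=float(s[1]), b=float(s[2]))


def apply_channel_scale(image, scale: ChannelScale) -> np.ndarray:
    """Rescale channels; output is float64, clipped to [0, 255].

    Before clipping, each output channel mean equals the reference mean
    exactly; clipping can introduce a small deviation, which is logged.
    """
    image = _check_rgb(image).astype(np.float64)
    out = image * scale.as_array()
    clipped = np.clip(out, 0.0, 255.0)
    dev = np.abs(clipped - out).max()
    if dev > 0:
        warnings.warn(
            f"channel scaling clipped values by up to {dev:.2f} intensity "
            "units; channel means may deviate from the reference"
        )
    return clipped


def aggregate_patient_features(per_tile_tables) -> pd.Series:
    """Per-patient feature vector: the median of each feature across tiles.

    ``per_tile_tables`` is a list of single-row feature tables (or a list
    of Series), one per tile, sharing identical feature columns. Missing
    values are excluded from that feature's median.
    """
    frames = []
    for t in per_tile_tables:
        if isinstance(t, pd.Series):
            frames.append(t.to_frame().T)
        else:
            frames.append(pd.DataFrame(t))
    if not frames:
        raise ValueError("no tile tables supplied")
    cols = list(frames[0].columns)
    for i, f in enumerate(frames[1:], start=1):
        if list(f.columns) != cols:
            missing = set(cols) ^ set(f.columns)
            raise ValueError(
                f"tile table {i} has mismatched feature columns: {sorted(missing)}"
            )
    stacked = pd.concat(frames, axis=0, ignore_index=True)
    return stacked.median(axis=0, skipna=True)
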