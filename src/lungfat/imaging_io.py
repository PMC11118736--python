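"""Reading, writing and windowing of 16-bit axial CT slices.

Slices are stored as single-channel 16-bit PNGs (the DeepLesion
convention); raw stored intensities are used directly, with no
Hounsfield calibration or offset handling.  Two per-slice intensity
normalizations are provided:

* ``max_intensity_norm`` — divide by the fixed 4095 intensity ceiling
  (values above 4095, possible in 16-bit storage, clip to 1.0);
* ``max_min_norm`` — per-slice min–max rescaling to [0, 1].

Segmentation masks travel as JSON polygon files.  Vertices are integer
pixel-corner coordinates — pixel (row r, column c) spans corners
(x=c, y=r) to (x=c+1, y=r+1) — and a pixel belongs to the mask when its
centre (c+0.5, r+0.5) has an odd winding count over all polygons
(even-odd rule).  Centres sit at half-integers so they never fall on a
polygon edge, which makes rasterization unambiguous and lets traced
masks round-trip exactly.

Localization labels are one CSV per volume with columns index,label
(0 = first lung slice, 1 = other, 2 = last lung slice).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

MAX_INTENSITY = 4095.0


class FormatError(ValueError):
    """Image file does not match the expected single-channel 16-bit form."""


class DegenerateSliceError(ValueError):
    """A per-slice statistic is undefined (e.g. constant image)."""


class LocalizationLabel(IntEnum):
    """Per-slice localization class: the three classes bracket the lung."""

    FIRST = 0
    OTHER = 1
    LAST = 2

    @property
    def onehot(self):
        v = np.zeros(3, dtype=np.float64)
        v[int(self)] = 1.0
        return v


@dataclass
class CTSlice:
    """One axial slice: raw non-negative integer pixels plus geometry.

    ``spacing_mm`` is the physical distance to the adjacent slices and
    ``index`` the 0-based position within its volume (0 = most superior).
    """

    pixels: np.ndarray
    spacing_mm: float
    index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected 2-D pixel array, got {self.pixels.ndim}-D")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel values must be non-negative")
        if self.spacing_mm <= 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")

    @property
    def height(self):
        return self.pixels.shape[0]

    @property
    def width(self):
        return self.pixels.shape[1]


@dataclass
class SliceWindow:
    """L consecutive slices (L odd, in {3,5,7}) labelled by the centre slice."""

    slices: list
    label: LocalizationLabel
    volume_id: str = ""

    def __post_init__(self):
        L = len(self.slices)
        if L not in (3, 5, 7):
            raise ValueError(f"window length must be one of 3, 5, 7; got {L}")
        idx = [s.index for s in self.slices]
        if idx != list(range(idx[0], idx[0] + L)):
            raise ValueError(f"slice indices must be consecutive, got {idx}")
        shapes = {s.pixels.shape for s in self.slices}
        spacings = {s.spacing_mm for s in self.slices}
        if len(shapes) != 1 or len(spacings) != 1:
            raise ValueError("all slices in a window must share shape and spacing")

    @property
    def center_index(self):
        return self.slices[len(self.slices) // 2].index


@dataclass
class SegSample:
    """One slice with the binary ground-truth mask of a single tissue."""

    image: CTSlice
    mask: np.ndarray
    tissue: str  # "SAT" or "VAT"

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        if self.mask.shape != self.image.pixels.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != image shape {self.image.pixels.shape}"
            )
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")
        if self.tissue not in ("SAT", "VAT"):
            raise ValueError(f"tissue must be SAT or VAT, got {self.tissue!r}")


# -- slice I/O ----------------------------------------------------------


def read_slice(path, spacing_mm, index=0):
    """Read a single-channel 16-bit PNG into a :class:`CTSlice`.

    Pixels are returned exactly as stored (no rescaling).
    """
    img = Image.open(path)
    if img.mode in ("RGB", "RGBA", "LA", "P", "CMYK", "YCbCr"):
        n_ch = len(img.getbands())
        raise FormatError(
            f"{path}: expected single-channel image, got {n_ch} channels ({img.mode})"
        )
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2-D image, got shape {arr.shape}")
    return CTSlice(pixels=arr.astype(np.int64), spacing_mm=spacing_mm, index=index)


def write_slice(slice_, path):
    """Write pixels as a 16-bit grayscale PNG (lossless round trip)."""
    arr = np.asarray(slice_.pixels)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("pixels out of 16-bit range")
    Image.fromarray(arr.astype(np.uint16)).save(path, format="PNG")
    return Path(path)


# -- normalizations -----------------------------------------------------


def max_intensity_norm(slice_):
    """Divide by the fixed 4095 ceiling; clip to 1.0 above it."""
    arr = slice_.pixels if isinstance(slice_, CTSlice) else np.asarray(slice_)
    return np.clip(arr.astype(np.float64) / MAX_INTENSITY, 0.0, 1.0)


def max_min_norm(slice_):
    """Per-slice (f - min f) / (max f - min f); output spans [0, 1]."""
    arr = slice_.pixels if isinstance(slice_, CTSlice) else np.asarray(slice_)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        idx = slice_.index if isinstance(slice_, CTSlice) else "?"
        raise DegenerateSliceError(
            f"slice {idx}: constant intensity ({lo}), min-max normalization undefined"
        )
    return (arr.astype(np.float64) - lo) / (hi - lo)


NORMALIZATIONS = {"MaxIntensity": max_intensity_norm, "MaxMinNorm": max_min_norm}


# -- windowing ----------------------------------------------------------


def make_windows(volume, labels, L, volume_id=""):
    """Slide a length-L window (stride 1) over an ordered volume.

    Each valid centre position yields one window labelled by its centre
    slice; end slices without a full surrounding window are skipped.
    """
    if L not in (3, 5, 7):
        raise ValueError(f"window length must be one of 3, 5, 7; got {L}")
    n = len(volume)
    if n < L:
        raise ValueError(f"volume has {n} slices; need at least {L} for L={L}")
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} slices")
    half = L // 2
    return [
        SliceWindow(
            slices=list(volume[c - half : c + half + 1]),
            label=LocalizationLabel(labels[c]),
            volume_id=volume_id,
        )
        for c in range(half, n - half)
    ]


# -- polygon masks ------------------------------------------------------


def rasterize_polygons(polygons, shape):
    """Even-odd rasterization of corner-coordinate polygons.

    A pixel is set when its centre lies inside an odd number of
    polygons.  Returns a (H, W) uint8 mask.
    """
    h, w = shape
    mask = np.zeros(shape, dtype=np.uint8)
    if not polygons:
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    for poly in polygons:
        pts = np.asarray(poly, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError(f"polygon must be a list of >=3 (x, y) pairs, got {poly!r}")
        if (pts[:, 0] < 0).any() or (pts[:, 0] > w).any() or (
            pts[:, 1] < 0
        ).any() or (pts[:, 1] > h).any():
            bad = pts[
                (pts[:, 0] < 0)
                | (pts[:, 0] > w)
                | (pts[:, 1] < 0)
                | (pts[:, 1] > h)
            ][0]
            raise ValueError(
                f"polygon vertex ({bad[0]:g}, {bad[1]:g}) outside {w}x{h} image bounds"
            )
        inside = MplPath(pts).contains_points(centers).reshape(shape)
        mask ^= inside.astype(np.uint8)
    return mask


def read_mask_labels(path, shape):
    """Read a JSON polygon mask file and rasterize it to `shape`.

    Schema: ``{"tissue": "SAT"|"VAT", "polygons": [[[x, y], ...], ...]}``.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}: malformed JSON mask file: {e}") from e
    if not isinstance(doc, dict) or "polygons" not in doc:
        raise ValueError(f"{path}: expected an object with a 'polygons' key")
    return rasterize_polygons(doc["polygons"], shape)


def write_mask_labels(polygons, tissue, path):
    with open(path, "w") as fh:
        json.dump({"tissue": tissue, "polygons": polygons}, fh)
    return Path(path)


# -- localization label CSV --------------------------------------------


def read_label_csv(path):
    """Read per-volume localization labels; returns index-ordered list."""
    rows = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            rows.append((int(row["index"]), LocalizationLabel(int(row["label"]))))
    rows.sort()
    return [lab for _, lab in rows]


def write_label_csv(labels, path):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "label"])
        for i, lab in enumerate(labels):
            writer.writerow([i, int(lab)])
    return Path(path)
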