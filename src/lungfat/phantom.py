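"""Synthetic chest-CT-like phantom volumes with known ground truth.

Each volume is an ordered stack of axial slices along the body axis.
An elliptical "body" of soft-tissue intensity carries a subcutaneous
fat ring (SAT) just inside its boundary, two low-intensity "lungs"
that appear at ``lung_first``, grow, shrink and vanish after
``lung_last`` (apex -> base -> apex area profile), and 2-6 irregular
visceral fat blobs (VAT) around the mediastinum on lung-bearing
slices.  Intensity bands on the [0, 4095] scale mimic CT ordering
(air < lung < fat < soft tissue) while remaining exactly separable at
zero noise:

==============  ============
background      0 - 100
lung interior   100 - 400
fat (SAT/VAT)   1400 - 1800
soft tissue     2200 - 2800
==============  ============

Absolute values are arbitrary — both training normalizations are
scale-free — but the ordering and contrast are what the localizer and
segmenter assume.  Geometry, labels and masks are fully determined by
a single integer seed.  The generator makes no attempt at anatomical
realism beyond this class topology (no ribs, vessels or pathology).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .imaging_io import (
    CTSlice,
    LocalizationLabel,
    write_label_csv,
    write_mask_labels,
    write_slice,
)

INTENSITY_BANDS = {
    "background": (0, 100),
    "lung": (100, 400),
    "fat": (1400, 1800),
    "soft_tissue": (2200, 2800),
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic volume.

    ``lung_first``/``lung_last`` are the indices of the first and last
    slices on which lungs are visible; they must leave at least one
    lung-free slice at each end of the stack.
    """

    n_slices: int = 12
    image_size: int = 64
    lung_first: int = 3
    lung_last: int = 8
    spacing_mm: float = 2.5
    noise_sd: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_slices < 7:
            raise ValueError(f"n_slices must be >= 7, got {self.n_slices}")
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if not (0 < self.lung_first < self.lung_last < self.n_slices - 1):
            raise ValueError(
                "need 0 < lung_first < lung_last < n_slices-1, got "
                f"lung_first={self.lung_first}, lung_last={self.lung_last}, "
                f"n_slices={self.n_slices}"
            )
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomVolume:
    slices: list
    loc_labels: list
    sat_masks: list
    vat_masks: list
    spec: PhantomSpec = None

    @property
    def volume_id(self):
        return f"phantom{self.spec.seed:05d}" if self.spec else "phantom"


def _lung_scale(i, fl, ll):
    """Unimodal lung size factor over [fl, ll]; zero outside."""
    if i < fl or i > ll:
        return 0.0
    u = (i - fl) / max(ll - fl, 1)
    return 0.45 + 0.55 * np.sin(np.pi * u)


def generate_volume(spec: PhantomSpec) -> PhantomVolume:
    """Render one phantom volume deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s]
    # normalized coordinates in [-1, 1] about the image centre
    x = (xx - (s - 1) / 2) / (s / 2)
    y = (yy - (s - 1) / 2) / (s / 2)

    # per-volume body geometry
    a = 0.86 + rng.uniform(-0.04, 0.04)  # horizontal semi-axis
    b = 0.72 + rng.uniform(-0.04, 0.04)  # vertical semi-axis
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    theta = np.arctan2(y / b, x / a)
    body = rho <= 1.0

    # SAT ring thickness varies smoothly around the perimeter
    phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
    thickness = 0.12 + 0.04 * np.sin(theta + phi1) + 0.03 * np.cos(2 * theta + phi2)
    sat_band = (rho <= 0.99) & (rho >= 0.99 - thickness)

    soft_base = rng.uniform(2400, 2600)
    fat_base = rng.uniform(1550, 1650)
    lung_base = rng.uniform(220, 280)
    bg_base = rng.uniform(30, 70)
    phi3 = rng.uniform(0, 2 * np.pi)
    texture = 120 * np.sin(3 * np.pi * x + phi3) * np.cos(2 * np.pi * y)

    slices, labels, sat_masks, vat_masks = [], [], [], []
    for i in range(spec.n_slices):
        scale = _lung_scale(i, spec.lung_first, spec.lung_last)
        lung = np.zeros((s, s), dtype=bool)
        if scale > 0:
            for sx in (-0.40, 0.40):
                lx = (x - sx * a) / (0.24 * a * scale)
                ly = (y + 0.04 * b) / (0.46 * b * scale)
                lung |= lx**2 + ly**2 <= 1.0
            lung &= rho <= 0.99 - thickness  # lungs never touch the SAT ring

        sat = sat_band & body
        vat = np.zeros((s, s), dtype=bool)
        if scale > 0:
            n_blobs = rng.integers(2, 7)
            for _ in range(n_blobs):
                cx = rng.uniform(-0.30, 0.30)
                cy = rng.uniform(-0.45, 0.50)
                r0 = rng.uniform(0.07, 0.15)
                ecc = rng.uniform(0.6, 1.4)
                wob_amp = rng.uniform(0.1, 0.35)
                wob_ph = rng.uniform(0, 2 * np.pi)
                bx = (x - cx) / r0
                by = (y - cy) / (r0 * ecc)
                ang = np.arctan2(by, bx)
                rad = 1.0 + wob_amp * np.sin(3 * ang + wob_ph)
                vat |= bx**2 + by**2 <= rad**2
            vat &= rho <= 0.99 - thickness  # interior only: disjoint from SAT
            vat &= ~lung

        img = np.full((s, s), bg_base + 0.2 * texture)
        img[body] = soft_base + texture[body]
        img[sat] = fat_base + 0.5 * texture[sat]
        img[vat] = fat_base + 0.5 * texture[vat]
        img[lung] = lung_base + 0.3 * texture[lung]
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=(s, s))
        img = np.clip(np.rint(img), 0, 4095).astype(np.int64)

        if i == spec.lung_first:
            lab = LocalizationLabel.FIRST
        elif i == spec.lung_last:
            lab = LocalizationLabel.LAST
        else:
            lab = LocalizationLabel.OTHER

        slices.append(CTSlice(pixels=img, spacing_mm=spec.spacing_mm, index=i))
        labels.append(lab)
        sat_masks.append(sat.astype(np.uint8))
        vat_masks.append(vat.astype(np.uint8))

    return PhantomVolume(slices, labels, sat_masks, vat_masks, spec=spec)


# -- mask <-> polygon tracing ------------------------------------------


def mask_to_polygons(mask):
    """Trace a binary mask into corner-coordinate polygons.

    The mask is represented exactly as the union of its unit pixel
    squares; exterior rings and hole rings are emitted as separate
    polygons so that even-odd rasterization reproduces the mask
    pixel-for-pixel.
    """
    rr, cc = np.nonzero(np.asarray(mask))
    if len(rr) == 0:
        return []
    boxes = shapely.box(cc, rr, cc + 1, rr + 1)
    geom = shapely.union_all(boxes)
    parts = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    polygons = []
    for part in parts:
        rings = [part.exterior, *part.interiors]
        for ring in rings:
            coords = list(ring.coords)[:-1]  # drop the closing duplicate
            polygons.append([[int(round(px)), int(round(py))] for px, py in coords])
    return polygons


def export_dataset(volume: PhantomVolume, directory) -> Path:
    """Write a volume in the on-disk dialects the readers consume.

    Per slice: a 16-bit PNG, a SAT polygon JSON and a VAT polygon JSON;
    plus one localization-label CSV.  Returns the manifest path (the
    manifest lists every data file, one per line).  A small meta.json
    (not listed in the manifest) records spacing and seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (sl, sat, vat) in enumerate(
        zip(volume.slices, volume.sat_masks, volume.vat_masks)
    ):
        png = f"slice_{i:03d}.png"
        write_slice(sl, directory / png)
        files.append(png)
        for tissue, msk in (("SAT", sat), ("VAT", vat)):
            name = f"slice_{i:03d}_{tissue.lower()}.json"
            write_mask_labels(mask_to_polygons(msk), tissue, directory / name)
            files.append(name)
    write_label_csv(volume.loc_labels, directory / "labels.csv")
    files.append("labels.csv")
    meta = {"spacing_mm": volume.slices[0].spacing_mm, "n_slices": len(volume.slices)}
    if volume.spec is not None:
        meta["seed"] = volume.spec.seed
    (directory / "meta.json").write_text(json.dumps(meta))
    manifest = directory / "manifest.txt"
    manifest.write_text("\n".join(files) + "\n")
    return manifest


def import_dataset(directory, spacing_mm=None) -> PhantomVolume:
    """Read back a directory written by :func:`export_dataset`."""
    from .imaging_io import read_label_csv, read_mask_labels, read_slice

    directory = Path(directory)
    meta_path = directory / "meta.json"
    if spacing_mm is None:
        if not meta_path.exists():
            raise ValueError("spacing_mm not given and no meta.json present")
        spacing_mm = json.loads(meta_path.read_text())["spacing_mm"]
    labels = read_label_csv(directory / "labels.csv")
    slices, sat_masks, vat_masks = [], [], []
    for i in range(len(labels)):
        sl = read_slice(directory / f"slice_{i:03d}.png", spacing_mm, index=i)
        shape = sl.pixels.shape
        slices.append(sl)
        sat_masks.append(read_mask_labels(directory / f"slice_{i:03d}_sat.json", shape))
        vat_masks.append(read_mask_labels(directory / f"slice_{i:03d}_vat.json", shape))
    return PhantomVolume(slices, labels, sat_masks, vat_masks, spec=None)


def generate_cohort(n_volumes, n_slices=12, image_size=64, spacing_mm=2.5,
                    noise_sd=50.0, seed=0):
    """Generate several volumes with randomized lung extents.

    Seeds are derived from ``seed`` via one parent stream so that the
    cohort is reproducible; lung_first/lung_last are drawn so that both
    fall on valid window-centre positions for L up to 7.
    """
    rng = np.random.default_rng(seed)
    vols = []
    for _ in range(n_volumes):
        # keep FIRST/LAST reachable as centres of 5-wide windows
        fl = int(rng.integers(2, max(n_slices // 2 - 1, 2) + 1))
        ll = int(rng.integers(n_slices // 2 + 1, max(n_slices - 3, n_slices // 2 + 1) + 1))
        sub = int(rng.integers(0, 2**31 - 1))
        vols.append(
            generate_volume(
                PhantomSpec(
                    n_slices=n_slices,
                    image_size=image_size,
                    lung_first=fl,
                    lung_last=ll,
                    spacing_mm=spacing_mm,
                    noise_sd=noise_sd,
                    seed=sub,
                )
            )
        )
    return vols
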