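"""Nucleus segmentation and geometric quality control.

The built-in segmenter is classical: Gaussian smoothing, Otsu threshold,
hole filling, 4-connected labeling, small-object removal. It is adequate for
synthetic and well-separated real nuclei; masks from external segmenters
(e.g. deep-learning models) can be imported as label TIFFs and flow through
the same measurement and QC path.

QC follows the convention that undersized or non-round "nuclei" are
segmentation errors: a nucleus is kept only if its equivalent circular
diameter is at least 10 um AND its circularity (4*pi*area/perimeter^2) is at
least 0.95. Perimeter is measured on the marching-squares contour after
Douglas-Peucker simplification (1 px tolerance), which tracks the analytic
perimeter of rasterized disks and squares well; circularity may slightly
exceed 1 for small objects and is not clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import remove_small_objects

from .images import DEFAULT_PIXEL_SIZE_UM, GrayImage

log = logging.getLogger(__name__)

MIN_DIAMETER_UM = 10.0
MIN_CIRCULARITY = 0.95


@dataclass(frozen=True)
class LabelMask:
    """Labeled nucleus mask: 0 = background, each nucleus a positive label."""

    labels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"expected 2D label mask, got shape {arr.shape}")
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", arr.astype(np.int32))

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def binary(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class NucleusRecord:
    """Per-nucleus geometry and QC verdict, in physical units."""

    label: int
    area_um2: float
    equivalent_diameter_um: float
    perimeter_um: float
    circularity: float
    centroid_x: float
    centroid_y: float
    touches_border: bool
    qc_pass: bool = True
    well: str = "A01"
    field: int = 1


def segment_nuclei(
    dapi: GrayImage,
    smooth_sigma: float = 2.0,
    min_area_px: int = 50,
) -> LabelMask:
    """Segment nuclei from a DAPI image (Otsu on a smoothed image).

    Returns an empty mask with a logged warning for constant images.
    """
    if dapi.is_constant():
        log.warning("constant DAPI image: returning empty mask")
        return LabelMask(np.zeros(dapi.shape, dtype=np.int32), dapi.pixel_size)
    smoothed = gaussian(dapi.pixels, sigma=smooth_sigma, preserve_range=True)
    binary = smoothed > threshold_otsu(smoothed)
    binary = ndimage.binary_fill_holes(binary)
    binary = remove_small_objects(binary, max_size=min_area_px - 1)
    labels, _ = ndimage.label(binary, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return LabelMask(labels, dapi.pixel_size)


def _contour_perimeter_px(mask_bool: np.ndarray, tolerance: float = 1.0) -> float:
    """Perimeter of a binary object from its simplified marching contour."""
    padded = np.pad(mask_bool.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        simplified = measure.approximate_polygon(contour, tolerance)
        total += float(np.sqrt(((simplified[1:] - simplified[:-1]) ** 2).sum(axis=1)).sum())
    return total


def measure_nucleus(
    mask: LabelMask, label: int, well: str = "A01", field: int = 1
) -> NucleusRecord:
    """Geometry of one labeled nucleus in physical units."""
    region = mask.labels == label
    n_px = int(region.sum())
    if n_px == 0:
        raise ValueError(f"label {label} not present in mask")
    px = mask.pixel_size
    area_um2 = n_px * px * px
    perimeter_um = _contour_perimeter_px(region) * px
    circularity = 4.0 * math.pi * area_um2 / perimeter_um**2 if perimeter_um > 0 else 0.0
    ys, xs = np.nonzero(region)
    h, w = mask.labels.shape
    touches = bool(ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1)
    return NucleusRecord(
        label=int(label),
        area_um2=area_um2,
        equivalent_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
        perimeter_um=perimeter_um,
        circularity=circularity,
        centroid_x=float(xs.mean()),
        centroid_y=float(ys.mean()),
        touches_border=touches,
        well=well,
        field=field,
    )


def measure_all(mask: LabelMask, well: str = "A01", field: int = 1) -> list[NucleusRecord]:
    return [measure_nucleus(mask, int(lab), well, field) for lab in mask.label_ids]


def qc_filter(
    records: list[NucleusRecord],
    min_diameter_um: float = MIN_DIAMETER_UM,
    min_circularity: float = MIN_CIRCULARITY,
    drop_border: bool = False,
) -> list[NucleusRecord]:
    """Mark nuclei failing the size or shape gate as QC failures.

    A nucleus fails if its equivalent diameter is below ``min_diameter_um``
    OR its circularity is below ``min_circularity`` (either condition marks
    a likely segmentation error). Border-touching nuclei are additionally
    dropped only when ``drop_border`` is set. Idempotent and
    order-independent; returns new records with ``qc_pass`` set.
    """
    out = []
    for rec in records:
        ok = (
            rec.equivalent_diameter_um >= min_diameter_um
            and rec.circularity >= min_circularity
            and not (drop_border and rec.touches_border)
        )
        out.append(replace(rec, qc_pass=ok))
    n_fail = sum(not r.qc_pass for r in out)
    if n_fail:
        log.info("QC removed %d/%d nuclei", n_fail, len(out))
    return out
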