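"""FISH spot detection by Laplacian-of-Gaussian filtering.

Diffraction-limited FISH spots are near-constant size, so detection is
single-scale: the image is filtered with a scale-normalized, sign-flipped
LoG (bright blobs give positive peaks), local maxima above a response
threshold are collected, and maxima closer than 2*sigma are merged keeping
the stronger response to avoid double-counting one site. Coordinates are
integer pixels; distances downstream are computed in microns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .images import GrayImage
from .segmentation import LabelMask


@dataclass(frozen=True)
class Spot:
    """A detected FISH signal and the nucleus that owns it (0 = none).

    ``radial`` and ``shell`` stay NaN/0 until the radial-positioning stage
    annotates the spot.
    """

    channel: str
    x: int
    y: int
    x_um: float
    y_um: float
    intensity: float
    log_response: float
    nucleus_label: int = 0
    well: str = "A01"
    field: int = 1
    radial: float = float("nan")
    shell: int = 0


def log_filter(img: GrayImage, sigma: float) -> np.ndarray:
    """Scale-normalized, sign-flipped Laplacian of Gaussian response.

    response = -sigma^2 * Laplacian(G_sigma * img). The Laplacian is the
    exact discrete 5-point stencil (not a truncated analytic kernel), so a
    constant image maps to exactly zero response and the response of an
    interior blob telescopes to ~0 over the full domain.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    smoothed = ndimage.gaussian_filter(img.pixels, sigma, mode="reflect")
    return -(sigma**2) * ndimage.laplace(smoothed, mode="reflect")


def detect_spots(
    img: GrayImage,
    sigma: float = 2.0,
    threshold: float | None = None,
    adaptive_k: float = 5.0,
    channel: str = "DNA",
    well: str = "A01",
    field: int = 1,
) -> list[Spot]:
    """Local maxima of the LoG response above a threshold.

    ``threshold`` is an absolute response value; when None, an adaptive
    per-image threshold mean + ``adaptive_k`` * sd of the response is used.
    Maxima within 2*sigma of a stronger maximum are suppressed; plateau ties
    resolve to the first pixel in row-major order. Output is sorted by
    (y, x).
    """
    resp = log_filter(img, sigma)
    if threshold is None:
        threshold = float(resp.mean() + adaptive_k * resp.std())
    elif threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")

    # local maxima incl. plateau members; merging below resolves plateaus
    local_max = resp == ndimage.maximum_filter(resp, size=3, mode="nearest")
    ys, xs = np.nonzero(local_max & (resp > threshold))
    if len(ys) == 0:
        return []

    responses = resp[ys, xs]
    # strongest first; equal responses in row-major order so the first
    # plateau pixel wins
    order = np.lexsort((xs, ys, -responses))
    ys, xs, responses = ys[order], xs[order], responses[order]

    min_d2 = (2.0 * sigma) ** 2
    kept: list[int] = []
    for i in range(len(ys)):
        ok = True
        for j in kept:
            if (ys[i] - ys[j]) ** 2 + (xs[i] - xs[j]) ** 2 < min_d2:
                ok = False
                break
        if ok:
            kept.append(i)

    px = img.pixel_size
    spots = [
        Spot(
            channel=channel,
            x=int(xs[i]),
            y=int(ys[i]),
            x_um=float(xs[i]) * px,
            y_um=float(ys[i]) * px,
            intensity=float(img.pixels[ys[i], xs[i]]),
            log_response=float(responses[i]),
            well=well,
            field=field,
        )
        for i in kept
    ]
    spots.sort(key=lambda s: (s.well, s.field, s.channel, s.y, s.x))
    return spots


def assign_spots_to_nuclei(spots: list[Spot], mask: LabelMask) -> list[Spot]:
    """Attach each spot to the nucleus label at its pixel.

    Spots landing on background (label 0) did not hybridize inside any
    nucleus and are removed.
    """
    out = []
    for s in spots:
        lab = int(mask.labels[s.y, s.x])
        if lab > 0:
            out.append(replace(s, nucleus_label=lab))
    return out
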