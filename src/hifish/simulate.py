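"""Synthetic FISH plate simulator with per-allele ground truth.

Emulates maximum-projected high-content fields: DAPI-stained nuclei (disks
or ellipses with low-frequency intensity texture so registration has
structure to lock onto), two DNA FISH spots per diploid nucleus, and one RNA
FISH spot per transcriptionally active allele placed within a configurable
radius (default 0.5 um) of its DNA spot. Spots are rendered as 2D Gaussians
(the widefield/confocal max-projection PSF approximation) on a constant
background, followed by optional Poisson shot noise and Gaussian read noise,
quantized to the 16-bit camera range.

Sequential mode emits two acquisitions sharing the DAPI stain: the DNA pass
(DAPI + DNA) and the RNA pass (DAPI + RNA) whose content is translated by a
configurable plate re-mounting shift and independently re-noised.

All randomness flows from one master seed: each (well, field) uses
``numpy.random.default_rng([seed, well_index, field_index])`` so fields are
reproducible independently of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .images import Acquisition, GrayImage, write_image
from .registration import apply_translation
from .segmentation import LabelMask
from .radial import radial_map

U16_MAX = 65535


@dataclass
class SimulationConfig:
    """Everything the simulator needs; defaults model the reference assay.

    Geometry is in pixels, physical quantities in microns. Defaults use the
    1x1-binning pixel size of 0.108 um/px and nuclei of ~11-13 um diameter,
    comfortably above the 10 um QC gate.
    """

    seed: int = 0
    image_size: int = 512
    pixel_size: float = 0.108
    n_nuclei: int = 4
    nucleus_radius_range: tuple[int, int] = (52, 60)
    nucleus_shape: str = "disk"  # disk | ellipse
    p_active: float = 0.3
    rna_offset_max_um: float = 0.5
    radial_model: str = "uniform_in_nucleus"  # or "beta"
    beta_params: tuple[float, float] = (5.0, 2.0)
    psf_sigma: float = 2.0
    spot_amplitude: float = 2000.0
    dapi_amplitude: float = 800.0
    background_level: float = 200.0
    noise_sigma: float = 50.0
    poisson_noise: bool = True
    sequential_shift: tuple[int, int] = (0, 0)
    stray_spot_rate: float = 0.0
    guarantee_spot_separation: bool = True
    n_fields: int = 1
    n_wells: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_active <= 1.0:
            raise ValueError("p_active must lie in [0, 1]")
        if not 0.0 < self.rna_offset_max_um < 1.0:
            raise ValueError(
                "rna_offset_max_um must lie in (0, 1) um so ground-truth active "
                "alleles are classifiable as Active"
            )

    def min_dna_separation_px(self) -> float:
        """Separation between the two DNA spots of one nucleus.

        Guarantees (a) every same-channel spot pair is >= 4 sigma apart so
        detections never merge, and (b) an inactive allele can never fall
        within the 1 um activity threshold of the sibling allele's RNA spot.
        """
        if not self.guarantee_spot_separation:
            return 0.0
        off_px = self.rna_offset_max_um / self.pixel_size
        optical = 4.0 * self.psf_sigma + 2.0 * off_px
        classif = (1.0 + self.rna_offset_max_um) / self.pixel_size + 2.0
        return max(optical, classif)


@dataclass
class AlleleTruth:
    well: str
    field: int
    nucleus_index: int
    dna_x: int
    dna_y: int
    true_radial: float
    active: bool
    rna_x: int | None
    rna_y: int | None


@dataclass
class NucleusTruth:
    well: str
    field: int
    nucleus_index: int
    center_x: float
    center_y: float
    radius_y: float
    radius_x: float


@dataclass
class GroundTruth:
    """Simulator truth for one field: geometry, alleles, injected shift."""

    nuclei: list[NucleusTruth]
    alleles: list[AlleleTruth]
    shift: tuple[int, int] = (0, 0)


def field_rng(seed: int, well_index: int = 0, field_index: int = 0) -> np.random.Generator:
    """Per-field generator derived from the master seed (documented scheme)."""
    return np.random.default_rng([int(seed), int(well_index), int(field_index)])


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator) -> list[tuple]:
    """Non-overlapping nucleus geometries (cy, cx, ry, rx); raises if crowded."""
    size = cfg.image_size
    lo, hi = cfg.nucleus_radius_range
    # fixed margin, independent of the protocol, so a simultaneous and a
    # sequential plate from the same seed share identical ground truth
    shift_mag = max(abs(cfg.sequential_shift[0]), abs(cfg.sequential_shift[1]))
    if shift_mag > 16:
        raise ValueError("sequential_shift magnitude must be <= 16 px")
    border = 20
    placed: list[tuple] = []
    for _ in range(cfg.n_nuclei):
        for attempt in range(1000):
            ry = float(rng.uniform(lo, hi))
            rx = ry if cfg.nucleus_shape == "disk" else float(rng.uniform(lo, hi))
            margin = max(ry, rx) + border
            if 2 * margin >= size:
                raise ValueError(
                    f"nucleus radius {max(ry, rx):.0f} px cannot fit in a "
                    f"{size} px field; use fewer/smaller nuclei or a larger field"
                )
            cy = float(rng.uniform(margin, size - margin))
            cx = float(rng.uniform(margin, size - margin))
            gap = 6.0
            if cfg.guarantee_spot_separation:
                # spots can sit on nucleus boundaries, so the inter-nucleus
                # gap must itself keep same-channel spots >= 4 sigma apart
                gap = max(gap, 4.0 * cfg.psf_sigma + 2.0)
            if all(
                math.hypot(cy - py, cx - px) > max(ry, rx) + max(pry, prx) + gap
                for py, px, pry, prx in placed
            ):
                placed.append((cy, cx, ry, rx))
                break
        else:
            raise ValueError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei in 1000 "
                "attempts; use fewer or smaller nuclei"
            )
    return placed


def _nucleus_mask(size: int, geom: tuple) -> np.ndarray:
    cy, cx, ry, rx = geom
    yy, xx = np.ogrid[:size, :size]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def place_spot_at_radius(
    nucleus_mask: np.ndarray,
    radial_values: np.ndarray,
    target_radial: float,
    rng: np.random.Generator,
    tol: float = 0.05,
) -> tuple[int, int]:
    """A pixel of the nucleus whose normalized radial value is near target.

    Uniform over the admissible ring |radial - target| <= tol. Returns
    (x, y); raises when no pixel reaches the target (tiny nuclei).
    """
    if not 0.0 <= target_radial <= 1.0:
        raise ValueError(f"target radial {target_radial} outside [0, 1]")
    if target_radial in (0.0, 1.0):
        # endpoints exist exactly: the deepest pixel(s) and the boundary ring
        ring = nucleus_mask & (radial_values == target_radial)
    else:
        ring = nucleus_mask & (np.abs(radial_values - target_radial) <= tol)
    ys, xs = np.nonzero(ring)
    if len(ys) == 0:
        raise ValueError(
            f"no pixel within {tol} of radial {target_radial}; nucleus too small"
        )
    i = int(rng.integers(len(ys)))
    return int(xs[i]), int(ys[i])


def _render_spots(size: int, spots_xy: list[tuple[float, float]], amp: float,
                  sigma: float) -> np.ndarray:
    img = np.zeros((size, size))
    half = int(math.ceil(4 * sigma))
    for x0, y0 in spots_xy:
        y0i, x0i = int(round(y0)), int(round(x0))
        ylo, yhi = max(0, y0i - half), min(size, y0i + half + 1)
        xlo, xhi = max(0, x0i - half), min(size, x0i + half + 1)
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        img[ylo:yhi, xlo:xhi] += amp * np.exp(
            -((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2)
        )
    return img


def _camera(noiseless: np.ndarray, cfg: SimulationConfig,
            rng: np.random.Generator) -> np.ndarray:
    img = np.clip(noiseless, 0, None)
    if cfg.poisson_noise:
        img = rng.poisson(img).astype(np.float64)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, U16_MAX)


def simulate_field(
    cfg: SimulationConfig,
    well: str = "A01",
    field: int = 1,
    well_index: int = 0,
    mode: str = "simultaneous",
) -> tuple[list[Acquisition], GroundTruth]:
    """Render one field and its ground truth.

    Returns one acquisition (DAPI/DNA/RNA) in simultaneous mode, or the
    [DNA-pass, RNA-pass] pair in sequential mode with the RNA pass content
    translated by ``cfg.sequential_shift`` and independently re-noised.
    """
    if mode not in ("simultaneous", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = field_rng(cfg.seed, well_index, field)
    size = cfg.image_size
    geoms = _place_nuclei(cfg, rng)

    # labeled ground-truth mask and its radial field (used for placement)
    labels = np.zeros((size, size), dtype=np.int32)
    for i, g in enumerate(geoms, start=1):
        labels[_nucleus_mask(size, g)] = i
    rmap = radial_map(LabelMask(labels, cfg.pixel_size))

    # DAPI: textured nuclei so cross-correlation has features to lock onto
    coarse = rng.normal(0.0, 1.0, (max(size // 16, 4),) * 2)
    texture = ndimage.zoom(coarse, size / coarse.shape[0], order=1)[:size, :size]
    texture = 0.35 * texture / max(np.abs(texture).max(), 1e-12)
    dapi_noiseless = cfg.background_level + cfg.dapi_amplitude * (labels > 0) * (1.0 + texture)
    dapi_noiseless = ndimage.gaussian_filter(dapi_noiseless, cfg.psf_sigma)

    min_sep = cfg.min_dna_separation_px()
    off_px = cfg.rna_offset_max_um / cfg.pixel_size
    nuclei_truth, alleles_truth = [], []
    dna_xy: list[tuple[float, float]] = []
    rna_xy: list[tuple[float, float]] = []

    for i, g in enumerate(geoms, start=1):
        cy, cx, ry, rx = g
        nuclei_truth.append(NucleusTruth(well, field, i, cx, cy, ry, rx))
        nmask = labels == i

        positions: list[tuple[int, int]] = []
        for _allele in range(2):
            for attempt in range(200):
                if cfg.radial_model == "beta":
                    a, b = cfg.beta_params
                    target = float(rng.beta(a, b))
                    x, y = place_spot_at_radius(nmask, rmap.values, target, rng)
                else:
                    ys, xs = np.nonzero(nmask)
                    j = int(rng.integers(len(ys)))
                    x, y = int(xs[j]), int(ys[j])
                if all(math.hypot(x - px, y - py) >= min_sep for px, py in positions):
                    positions.append((x, y))
                    break
            else:
                raise ValueError(
                    "could not separate two DNA spots; nucleus too small for the "
                    "configured separation guarantee"
                )

        for (x, y) in positions:
            active = bool(rng.random() < cfg.p_active)
            rxy: tuple[int, int] | None = None
            if active:
                for attempt in range(500):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = off_px * math.sqrt(rng.random())
                    qx = int(round(x + rad * math.cos(ang)))
                    qy = int(round(y + rad * math.sin(ang)))
                    if 0 <= qy < size and 0 <= qx < size and nmask[qy, qx]:
                        rxy = (qx, qy)
                        break
                if rxy is None:
                    rxy = (x, y)  # fall back to the DNA position (distance 0)
                rna_xy.append((float(rxy[0]), float(rxy[1])))
            dna_xy.append((float(x), float(y)))
            alleles_truth.append(
                AlleleTruth(
                    well, field, i, x, y, float(rmap.values[y, x]), active,
                    rxy[0] if rxy else None, rxy[1] if rxy else None,
                )
            )

        # optional stray spots (aneuploidy / detection-error emulation)
        if cfg.stray_spot_rate > 0:
            for channel_list in (dna_xy, rna_xy):
                for _ in range(rng.poisson(cfg.stray_spot_rate)):
                    ys, xs = np.nonzero(nmask)
                    j = int(rng.integers(len(ys)))
                    channel_list.append((float(xs[j]), float(ys[j])))

    dna_noiseless = cfg.background_level + _render_spots(
        size, dna_xy, cfg.spot_amplitude, cfg.psf_sigma
    )
    rna_noiseless = cfg.background_level + _render_spots(
        size, rna_xy, cfg.spot_amplitude, cfg.psf_sigma
    )

    px = cfg.pixel_size
    if mode == "simultaneous":
        acq = Acquisition(
            {
                "DAPI": GrayImage(_camera(dapi_noiseless, cfg, rng), px),
                "DNA": GrayImage(_camera(dna_noiseless, cfg, rng), px),
                "RNA": GrayImage(_camera(rna_noiseless, cfg, rng), px),
            },
            well=well,
            field=field,
        )
        return [acq], GroundTruth(nuclei_truth, alleles_truth, (0, 0))

    shift = (int(cfg.sequential_shift[0]), int(cfg.sequential_shift[1]))
    dna_acq = Acquisition(
        {
            "DAPI": GrayImage(_camera(dapi_noiseless, cfg, rng), px),
            "DNA": GrayImage(_camera(dna_noiseless, cfg, rng), px),
        },
        well=well,
        field=field,
    )
    dapi_shifted = apply_translation(GrayImage(dapi_noiseless, px), shift)
    rna_shifted = apply_translation(GrayImage(rna_noiseless, px), shift)
    rna_acq = Acquisition(
        {
            "DAPI": GrayImage(_camera(dapi_shifted.pixels, cfg, rng), px),
            "RNA": GrayImage(_camera(rna_shifted.pixels, cfg, rng), px),
        },
        well=well,
        field=field,
        metadata={"injected_shift": shift},
    )
    return [dna_acq, rna_acq], GroundTruth(nuclei_truth, alleles_truth, shift)


def well_names(n: int) -> list[str]:
    """A01, A02, ... following 384-well plate row-major order."""
    rows = "ABCDEFGHIJKLMNOP"
    return [f"{rows[i // 24]}{i % 24 + 1:02d}" for i in range(n)]


def simulate_plate(
    cfg: SimulationConfig,
    out_dir: str | Path,
    mode: str = "simultaneous",
    overwrite: bool = False,
) -> Path:
    """Write a plate of TIFF fields plus per-well ground-truth CSVs.

    Layout: ``<out>/<well>/<well>_f<field>_<channel>_<acq>.tif`` with acq
    ``single`` (simultaneous) or ``dna_pass``/``rna_pass`` (sequential);
    ground truth as ``<out>/<well>/gt_alleles.csv`` / ``gt_nuclei.csv``;
    the config serialized to ``<out>/sim_config.yaml``.
    """
    import pandas as pd

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    for wi, well in enumerate(well_names(cfg.n_wells)):
        wdir = out / well
        wdir.mkdir(exist_ok=True)
        gt_alleles, gt_nuclei = [], []
        for f in range(1, cfg.n_fields + 1):
            acqs, gt = simulate_field(cfg, well, f, wi, mode)
            if mode == "simultaneous":
                tags = [("single", acqs[0])]
            else:
                tags = [("dna_pass", acqs[0]), ("rna_pass", acqs[1])]
            for tag, acq in tags:
                for chan, img in acq.channels.items():
                    write_image(wdir / f"{well}_f{f}_{chan}_{tag}.tif", img)
            gt_alleles.extend(asdict(a) for a in gt.alleles)
            gt_nuclei.extend(asdict(n) for n in gt.nuclei)
        pd.DataFrame(gt_alleles).to_csv(wdir / "gt_alleles.csv", index=False)
        pd.DataFrame(gt_nuclei).to_csv(wdir / "gt_nuclei.csv", index=False)

    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump({**asdict(cfg), "mode": mode}, fh)
    return out
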