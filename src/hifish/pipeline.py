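"""End-to-end pipeline: fields in, allele tables out.

The simultaneous protocol images DAPI/DNA/RNA in one pass; the sequential
protocol images two passes sharing DAPI, so it runs translation registration
first. Both then share the same tail: nucleus segmentation and QC, LoG spot
detection per channel, spot-to-nucleus assignment, radial positioning, cell
selection, DNA-RNA distances and Active/Inactive/NoTranscription
classification, and per-group radial summaries.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import __version__
from .alleles import (
    AlleleRecord,
    CellRecord,
    classify_allele,
    count_and_bin,
    min_dna_rna_distance,
    summarize_radial,
)
from .images import Acquisition
from .radial import radial_map, radial_of_spot, shell_bin
from .registration import register_acquisition
from .segmentation import NucleusRecord, measure_all, qc_filter, segment_nuclei
from .spots import Spot, assign_spots_to_nuclei, detect_spots

log = logging.getLogger(__name__)

MODES = ("simultaneous", "sequential")


@dataclass
class RunConfig:
    """Tunable parameters of one analysis run (defaults = reference assay)."""

    pixel_size_um: float = 0.108
    mode: str = "simultaneous"
    max_shift: int | None = None  # None -> 10% of the smaller image dimension
    smooth_sigma: float = 2.0
    min_nucleus_area_px: int = 50
    min_diameter_um: float = 10.0
    min_circularity: float = 0.95
    drop_border: bool = False
    log_sigma: float = 2.0
    spot_threshold: float | None = None  # None -> adaptive mean + k*sd
    adaptive_k: float = 5.0
    activity_threshold_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("pixel_size_um", "min_diameter_um", "min_circularity",
                     "activity_threshold_um", "log_sigma", "smooth_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    """All tables of one run, as tidy DataFrames with stable columns."""

    nuclei: pd.DataFrame
    cells: pd.DataFrame
    spots: pd.DataFrame
    alleles: pd.DataFrame
    summaries: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _effective_max_shift(acq: Acquisition, cfg: RunConfig) -> int:
    if cfg.max_shift is not None:
        return cfg.max_shift
    img = acq["DAPI"]
    return max(1, min(img.height, img.width) // 10)


def analyze_field(acq: Acquisition, cfg: RunConfig):
    """Run the shared analysis tail on one registered acquisition."""
    mask = segment_nuclei(acq["DAPI"], cfg.smooth_sigma, cfg.min_nucleus_area_px)
    nuclei = qc_filter(
        measure_all(mask, acq.well, acq.field),
        cfg.min_diameter_um,
        cfg.min_circularity,
        cfg.drop_border,
    )
    rmap = radial_map(mask)
    spots = []
    for chan in ("DNA", "RNA"):
        if chan not in acq:
            continue
        detected = detect_spots(
            acq[chan], cfg.log_sigma, cfg.spot_threshold, cfg.adaptive_k,
            channel=chan, well=acq.well, field=acq.field,
        )
        for s in assign_spots_to_nuclei(detected, mask):
            r = radial_of_spot(s, rmap)
            spots.append(replace(s, radial=r, shell=shell_bin(r)))

    cells = count_and_bin(spots, nuclei)
    alleles = _alleles_from_spots(cells, spots, cfg)
    return nuclei, cells, spots, alleles


def _alleles_from_spots(cells, spots, cfg: RunConfig) -> list[AlleleRecord]:
    """Allele records from radial-annotated, nucleus-assigned spots."""
    by_cell: dict[tuple, dict[str, list]] = {}
    for s in spots:
        key = (s.well, s.field, s.nucleus_label)
        by_cell.setdefault(key, {"DNA": [], "RNA": []})[s.channel].append(s)
    alleles: list[AlleleRecord] = []
    for cell in cells:
        if not cell.analyzable:
            continue
        cell_spots = by_cell.get(
            (cell.well, cell.field, cell.nucleus_label), {"DNA": [], "RNA": []}
        )
        dists = min_dna_rna_distance(cell, cell_spots["DNA"], cell_spots["RNA"])
        for dna_spot, dist in zip(cell_spots["DNA"], dists):
            alleles.append(
                AlleleRecord(
                    well=cell.well,
                    field=cell.field,
                    nucleus_label=cell.nucleus_label,
                    dna_x_um=dna_spot.x_um,
                    dna_y_um=dna_spot.y_um,
                    min_rna_distance_um=dist,
                    status=classify_allele(dist, cfg.activity_threshold_um),
                    radial=dna_spot.radial,
                    shell=dna_spot.shell,
                )
            )
    return alleles


def analyze_tables(
    spots: pd.DataFrame, nuclei: pd.DataFrame, config: RunConfig | None = None
) -> PipelineResult:
    """Allele analysis from previously written spot and nucleus tables.

    ``spots`` must be nucleus-assigned and carry the radial/shell columns the
    detection+radial stages append; ``nuclei`` must carry ``qc_pass``.
    """
    cfg = config or RunConfig()
    nucleus_records = [NucleusRecord(**row) for row in
                       nuclei[NUCLEUS_COLUMNS].to_dict("records")]
    spot_records = [Spot(**row) for row in spots[SPOT_COLUMNS].to_dict("records")]
    cells = count_and_bin(spot_records, nucleus_records)
    alleles = _alleles_from_spots(cells, spot_records, cfg)
    summaries = summarize_radial(alleles)
    return PipelineResult(
        nuclei=_frame(nucleus_records, NUCLEUS_COLUMNS),
        cells=_frame(cells, CELL_COLUMNS),
        spots=_frame(spot_records, SPOT_COLUMNS),
        alleles=_frame(alleles, ALLELE_COLUMNS),
        summaries=_frame(summaries, SUMMARY_COLUMNS),
        manifest={"tool_version": __version__, "mode": cfg.mode,
                  "config": asdict(cfg), "source": "tables"},
    )


def run_pipeline(
    acquisitions, mode: str = "simultaneous", config: RunConfig | None = None
) -> PipelineResult:
    """Analyze a set of fields end to end.

    ``acquisitions`` is a list of :class:`Acquisition` in simultaneous mode,
    or a list of (DNA-pass, RNA-pass) pairs in sequential mode (registration
    is estimated per field from the shared DAPI channels).
    """
    cfg = config or RunConfig(mode=mode)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")

    all_nuclei, all_cells, all_spots, all_alleles = [], [], [], []
    registrations = []
    for item in acquisitions:
        if mode == "sequential":
            if not isinstance(item, (tuple, list)) or len(item) != 2:
                raise ValueError(
                    "sequential mode requires (DNA-pass, RNA-pass) acquisition pairs"
                )
            dna_acq, rna_acq = item
            acq = register_acquisition(dna_acq, rna_acq, _effective_max_shift(dna_acq, cfg))
            registrations.append({"well": acq.well, "field": acq.field,
                                  **acq.metadata["registration"]})
        else:
            if isinstance(item, (tuple, list)):
                raise ValueError("simultaneous mode takes single acquisitions, not pairs")
            acq = item
        nuclei, cells, spots, alleles = analyze_field(acq, cfg)
        all_nuclei.extend(nuclei)
        all_cells.extend(cells)
        all_spots.extend(spots)
        all_alleles.extend(alleles)
        log.info(
            "%s/f%d: %d nuclei (%d QC-pass), %d spots, %d analyzable cells",
            acq.well, acq.field, len(nuclei), sum(n.qc_pass for n in nuclei),
            len(spots), sum(c.analyzable for c in cells),
        )

    summaries = summarize_radial(all_alleles)
    manifest = {
        "tool_version": __version__,
        "mode": mode,
        "config": asdict(cfg),
        "n_fields": len(acquisitions),
        "registrations": registrations,
    }
    return PipelineResult(
        nuclei=_frame(all_nuclei, NUCLEUS_COLUMNS),
        cells=_frame(all_cells, CELL_COLUMNS),
        spots=_frame(all_spots, SPOT_COLUMNS),
        alleles=_frame(all_alleles, ALLELE_COLUMNS),
        summaries=_frame(summaries, SUMMARY_COLUMNS),
        manifest=manifest,
    )


NUCLEUS_COLUMNS = [
    "well", "field", "label", "area_um2", "equivalent_diameter_um",
    "perimeter_um", "circularity", "centroid_x", "centroid_y",
    "touches_border", "qc_pass",
]
CELL_COLUMNS = [
    "well", "field", "nucleus_label", "n_dna", "n_rna", "dna_bin", "rna_bin",
    "analyzable",
]
SPOT_COLUMNS = [
    "well", "field", "channel", "x", "y", "x_um", "y_um", "intensity",
    "log_response", "nucleus_label", "radial", "shell",
]
ALLELE_COLUMNS = [
    "well", "field", "nucleus_label", "dna_x_um", "dna_y_um",
    "min_rna_distance_um", "status", "radial", "shell",
]
SUMMARY_COLUMNS = ["group", "n_alleles", "mean_radial", "sd_radial", "shell_histogram"]


def _frame(records, columns) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame([asdict(r) for r in records])
    return df[columns]


def active_fraction(alleles: pd.DataFrame) -> float:
    """Fraction of alleles classified Active (NaN for an empty table)."""
    if len(alleles) == 0:
        return float("nan")
    return float((alleles["status"] == "Active").mean())


def match_alleles_to_truth(
    alleles: pd.DataFrame, truth: pd.DataFrame, pixel_size: float, tol_px: float = 3.0
) -> pd.DataFrame:
    """Join pipeline alleles to simulator ground truth by DNA spot position.

    Greedy nearest match per (well, field); unmatched rows on either side are
    dropped. Returns the allele table with ``true_active`` attached.
    """
    rows = []
    for (well, fld), sub in alleles.groupby(["well", "field"]):
        tsub = truth[(truth["well"] == well) & (truth["field"] == fld)]
        if len(tsub) == 0:
            continue
        tx = tsub["dna_x"].to_numpy() * pixel_size
        ty = tsub["dna_y"].to_numpy() * pixel_size
        used = np.zeros(len(tsub), dtype=bool)
        for _, row in sub.iterrows():
            d = np.hypot(tx - row["dna_x_um"], ty - row["dna_y_um"])
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= tol_px * pixel_size:
                used[j] = True
                r = row.to_dict()
                r["true_active"] = bool(tsub.iloc[j]["active"])
                r["true_radial"] = float(tsub.iloc[j]["true_radial"])
                rows.append(r)
    return pd.DataFrame(rows)
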