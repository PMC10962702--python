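"""Allele-level accounting: cell selection, DNA-RNA distances, activity.

A diploid nucleus carries two copies (alleles) of the probed locus, each one
DNA FISH spot. Cells are analyzable only when exactly 2 DNA spots and at
most 2 RNA spots were detected; other counts indicate segmentation or
detection errors (or aneuploidy) and the cell is excluded entirely. For each
DNA spot in an analyzable cell, the minimum Euclidean distance (in microns,
2D on the maximum projection) to any RNA spot in the same cell determines
its status:

* no RNA spot in the cell  -> distance NA -> "NoTranscription"
* distance < 1.0 um        -> "Active" (nascent transcription at the locus)
* otherwise                -> "Inactive"

One RNA spot may validate both DNA spots when within the threshold of both;
no one-to-one matching is enforced. Radial distributions of allele groups
are compared with a two-sided two-sample Kolmogorov-Smirnov test, exact by
enumeration for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import kstwobign

from .segmentation import NucleusRecord
from .spots import Spot

ACTIVITY_THRESHOLD_UM = 1.0
STATUS_ACTIVE = "Active"
STATUS_INACTIVE = "Inactive"
STATUS_NONE = "NoTranscription"

EXACT_KS_MAX_PRODUCT = 100


def _bin_count(n: int) -> str:
    return str(n) if n < 3 else ">=3"


@dataclass
class CellRecord:
    """Per-cell spot counts and the analyzability verdict."""

    well: str
    field: int
    nucleus_label: int
    n_dna: int
    n_rna: int
    dna_bin: str = ""
    rna_bin: str = ""
    analyzable: bool = False

    def __post_init__(self) -> None:
        self.dna_bin = _bin_count(self.n_dna)
        self.rna_bin = _bin_count(self.n_rna)
        self.analyzable = self.n_dna == 2 and self.n_rna <= 2


@dataclass
class AlleleRecord:
    """One DNA FISH spot with its activity status and radial position."""

    well: str
    field: int
    nucleus_label: int
    dna_x_um: float
    dna_y_um: float
    min_rna_distance_um: float | None
    status: str
    radial: float = float("nan")
    shell: int = 0


@dataclass
class RadialSummary:
    """Radial statistics for one allele group."""

    group: str
    n_alleles: int
    mean_radial: float
    sd_radial: float
    shell_histogram: list[int] = field(default_factory=lambda: [0] * 5)


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    exact: bool


def count_and_bin(spots: list[Spot], nuclei: list[NucleusRecord]) -> list[CellRecord]:
    """Spot counts per QC-passing cell and channel, binned 0/1/2/>=3.

    ``spots`` must already be nucleus-assigned; spots in QC-failed nuclei
    are dropped along with their cells.
    """
    counts: dict[tuple[str, int, int], dict[str, int]] = {}
    for nuc in nuclei:
        if nuc.qc_pass:
            counts[(nuc.well, nuc.field, nuc.label)] = {"DNA": 0, "RNA": 0}
    for s in spots:
        key = (s.well, s.field, s.nucleus_label)
        if key in counts and s.channel in counts[key]:
            counts[key][s.channel] += 1
    return [
        CellRecord(well=w, field=f, nucleus_label=lab, n_dna=c["DNA"], n_rna=c["RNA"])
        for (w, f, lab), c in sorted(counts.items())
    ]


def min_dna_rna_distance(
    cell: CellRecord, dna_spots: list[Spot], rna_spots: list[Spot]
) -> list[float | None]:
    """Per-DNA-spot minimum Euclidean distance (um) to any RNA spot.

    All pairwise DNA-RNA distances within the cell are formed and the
    minimum taken per DNA spot; cells with no RNA spot get NA for every
    DNA spot.
    """
    if not cell.analyzable:
        raise ValueError(
            f"cell {cell.well}/f{cell.field}/n{cell.nucleus_label} is not analyzable "
            f"(n_dna={cell.n_dna}, n_rna={cell.n_rna})"
        )
    out: list[float | None] = []
    for d in dna_spots:
        if not rna_spots:
            out.append(None)
            continue
        out.append(
            min(math.hypot(d.x_um - r.x_um, d.y_um - r.y_um) for r in rna_spots)
        )
    return out


def classify_allele(
    distance_um: float | None, threshold_um: float = ACTIVITY_THRESHOLD_UM
) -> str:
    """Activity class of one allele from its minimum DNA-RNA distance."""
    if distance_um is None or (isinstance(distance_um, float) and math.isnan(distance_um)):
        return STATUS_NONE
    if distance_um < 0:
        raise ValueError(f"distance must be non-negative, got {distance_um}")
    return STATUS_ACTIVE if distance_um < threshold_um else STATUS_INACTIVE


def summarize_radial(
    alleles: list[AlleleRecord], grouping=lambda a: a.status
) -> list[RadialSummary]:
    """Mean/sd radial and the shell histogram per allele group.

    Groups with no alleles are omitted; singleton groups report sd 0.
    """
    groups: dict[str, list[AlleleRecord]] = {}
    for a in alleles:
        groups.setdefault(str(grouping(a)), []).append(a)
    out = []
    for name in sorted(groups):
        vals = np.array([a.radial for a in groups[name]], dtype=float)
        hist = [0] * 5
        for a in groups[name]:
            if 1 <= a.shell <= 5:
                hist[a.shell - 1] += 1
        out.append(
            RadialSummary(
                group=name,
                n_alleles=len(vals),
                mean_radial=float(vals.mean()),
                sd_radial=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                shell_histogram=hist,
            )
        )
    return out


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF_x - ECDF_y| over the pooled sample points."""
    pooled = np.concatenate([x, y])
    pooled.sort(kind="mergesort")
    cdf_x = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
    cdf_y = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
    return float(np.abs(cdf_x - cdf_y).max())


def _exact_p_value(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """P(D >= d_obs) by enumeration of all group assignments of the pool.

    Under the null every way of splitting the pooled sample into groups of
    sizes n1 and n2 is equally likely; the p-value is the fraction of splits
    whose statistic reaches the observed one. Vectorized over assignments.
    """
    n1, n2 = len(x), len(y)
    n = n1 + n2
    combos = np.fromiter(
        (i for c in combinations(range(n), n1) for i in c), dtype=np.intp
    ).reshape(-1, n1)
    # indicator over pooled *sorted* positions: pooled order is fixed, each
    # split chooses which sorted positions belong to sample 1
    ind = np.zeros((len(combos), n), dtype=np.float64)
    np.put_along_axis(ind, combos, 1.0, axis=1)
    cum1 = np.cumsum(ind, axis=1)
    pos = np.arange(1, n + 1)
    d_all = np.abs(cum1 / n1 - (pos - cum1) / n2)

    # with ties, the ECDF difference is only evaluated at the last pooled
    # position of each tied value
    pooled = np.sort(np.concatenate([x, y]))
    last_of_run = np.ones(n, dtype=bool)
    last_of_run[:-1] = pooled[:-1] != pooled[1:]
    d_split = d_all[:, last_of_run].max(axis=1)
    return float(np.mean(d_split >= d_obs - 1e-12))


def ks_two_sample(
    x, y, exact_max_product: int = EXACT_KS_MAX_PRODUCT
) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    The p-value is exact (enumeration of all splits of the pooled sample)
    when n1*n2 <= ``exact_max_product``, else asymptotic from the Kolmogorov
    distribution with the standard effective-sample-size correction
    sqrt(en) + 0.12 + 0.11/sqrt(en), en = n1*n2/(n1+n2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    n1, n2 = len(x), len(y)
    if n1 * n2 <= exact_max_product:
        p = _exact_p_value(x, y, d)
        return KSResult(d, p, n1, n2, exact=True)
    en = math.sqrt(n1 * n2 / (n1 + n2))
    p = float(kstwobign.sf((en + 0.12 + 0.11 / en) * d))
    return KSResult(d, min(max(p, 0.0), 1.0), n1, n2, exact=False)
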