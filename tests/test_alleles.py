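"""Cell selection, DNA-RNA distances, activity classes, and the KS test."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from hifish import (
    CellRecord,
    NucleusRecord,
    Spot,
    classify_allele,
    count_and_bin,
    ks_two_sample,
    min_dna_rna_distance,
    summarize_radial,
)
from hifish.alleles import AlleleRecord


def _nucleus(label, qc=True, well="A01", field=1):
    return NucleusRecord(label=label, area_um2=100, equivalent_diameter_um=12,
                         perimeter_um=35, circularity=0.99, centroid_x=0,
                         centroid_y=0, touches_border=False, qc_pass=qc,
                         well=well, field=field)


def _spot(channel, label, x=0, y=0, pixel_size=0.108, well="A01", field=1):
    return Spot(channel=channel, x=x, y=y, x_um=x * pixel_size,
                y_um=y * pixel_size, intensity=1000, log_response=50,
                nucleus_label=label, well=well, field=field)


class TestCountAndBin:
    def test_binning_and_analyzable_rule(self):
        spots = (
            [_spot("DNA", 1)] * 3
            + [_spot("DNA", 2)] * 2
            + [_spot("RNA", 2)]
            + [_spot("DNA", 3)] * 2 + [_spot("RNA", 3)] * 3
        )
        cells = {c.nucleus_label: c for c in
                 count_and_bin(spots, [_nucleus(1), _nucleus(2), _nucleus(3)])}
        assert cells[1].dna_bin == ">=3" and not cells[1].analyzable
        assert cells[2].dna_bin == "2" and cells[2].rna_bin == "1"
        assert cells[2].analyzable
        assert cells[3].rna_bin == ">=3" and not cells[3].analyzable

    def test_two_dna_zero_rna_is_analyzable(self):
        cells = count_and_bin([_spot("DNA", 1)] * 2, [_nucleus(1)])
        assert cells[0].analyzable and cells[0].rna_bin == "0"

    def test_empty_cell_binned_zero(self):
        (cell,) = count_and_bin([], [_nucleus(1)])
        assert (cell.dna_bin, cell.rna_bin, cell.analyzable) == ("0", "0", False)

    def test_qc_failed_nuclei_excluded(self):
        cells = count_and_bin([_spot("DNA", 1)], [_nucleus(1, qc=False), _nucleus(2)])
        assert [c.nucleus_label for c in cells] == [2]


class TestMinDnaRnaDistance:
    def test_three_four_five_triangle(self):
        cell = CellRecord("A01", 1, 1, n_dna=2, n_rna=1)
        dna = [_spot("DNA", 1, 0, 0), _spot("DNA", 1, 30, 0)]
        rna = [_spot("RNA", 1, 3, 4)]
        d = min_dna_rna_distance(cell, dna, rna)
        assert d[0] == pytest.approx(5 * 0.108)

    def test_no_rna_gives_na_for_both(self):
        cell = CellRecord("A01", 1, 1, n_dna=2, n_rna=0)
        d = min_dna_rna_distance(cell, [_spot("DNA", 1), _spot("DNA", 1)], [])
        assert d == [None, None]

    def test_matches_brute_force_all_pairs(self, rng):
        for _ in range(20):
            pts = rng.uniform(0, 100, (4, 2))
            dna = [_spot("DNA", 1, int(x), int(y)) for x, y in pts[:2]]
            rna = [_spot("RNA", 1, int(x), int(y)) for x, y in pts[2:]]
            cell = CellRecord("A01", 1, 1, n_dna=2, n_rna=2)
            got = min_dna_rna_distance(cell, dna, rna)
            for i, d in enumerate(dna):
                expect = min(math.hypot(d.x_um - r.x_um, d.y_um - r.y_um) for r in rna)
                assert got[i] == pytest.approx(expect)

    def test_non_analyzable_cell_is_error(self):
        cell = CellRecord("A01", 1, 1, n_dna=3, n_rna=0)
        with pytest.raises(ValueError, match="not analyzable"):
            min_dna_rna_distance(cell, [], [])


class TestClassifyAllele:
    @pytest.mark.parametrize(
        "distance,status",
        [(0.54, "Active"), (None, "NoTranscription"), (1.0, "Inactive"),
         (0.999, "Active"), (2.5, "Inactive")],
    )
    def test_threshold_semantics(self, distance, status):
        assert classify_allele(distance) == status

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            classify_allele(-0.1)


def _allele(status="Active", radial=0.5, shell=3):
    return AlleleRecord(well="A01", field=1, nucleus_label=1, dna_x_um=0,
                        dna_y_um=0, min_rna_distance_um=0.5, status=status,
                        radial=radial, shell=shell)


class TestSummarizeRadial:
    def test_singleton_group_reports_sd_zero(self):
        (s,) = summarize_radial([_allele(radial=0.6, shell=3)])
        assert s.n_alleles == 1 and s.mean_radial == 0.6 and s.sd_radial == 0.0

    def test_boundary_spots_mean_one(self):
        out = summarize_radial([_allele(radial=1.0, shell=5)] * 8)
        assert out[0].mean_radial == 1.0
        assert out[0].shell_histogram == [0, 0, 0, 0, 8]

    def test_histogram_conserves_alleles(self, rng):
        alleles = [_allele(radial=r, shell=min(int(r / 0.2) + 1, 5))
                   for r in rng.random(100)]
        (s,) = summarize_radial(alleles)
        assert sum(s.shell_histogram) == s.n_alleles == 100


class TestKsTwoSample:
    def test_identical_samples(self):
        x = [0.1, 0.4, 0.4, 0.9]
        res = ks_two_sample(x, list(x))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_supports_give_d_one(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_exact_p_matches_independent_oracle_small_n(self, rng):
        for n1, n2 in [(3, 3), (4, 5), (5, 5), (2, 10), (7, 7)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0.5, 1, n2)
            res = ks_two_sample(x, y)
            assert res.exact
            ref = ks_2samp(x, y, method="exact")
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_handles_ties(self, rng):
        x = np.array([0.0, 0.5, 0.5, 1.0])
        y = np.array([0.5, 0.5, 1.0, 1.5])
        res = ks_two_sample(x, y)
        # oracle: brute-force enumeration over labelled permutations
        from itertools import combinations
        pooled = np.concatenate([x, y])
        n = len(pooled)
        count = total = 0
        for idx in combinations(range(n), len(x)):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(n) if i not in idx]]
            grid = np.unique(pooled)
            d = np.abs(
                np.searchsorted(np.sort(xs), grid, side="right") / len(xs)
                - np.searchsorted(np.sort(ys), grid, side="right") / len(ys)
            ).max()
            count += d >= res.statistic - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_asymptotic_branch_close_to_reference(self, rng):
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.3, 1, 90)
        res = ks_two_sample(x, y)
        assert not res.exact
        ref = ks_2samp(x, y, method="asymp")
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.2, abs=0.02)
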