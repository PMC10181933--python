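"""Binned positivity, category recurrence and ecDNA co-occurrence."""

import numpy as np
import pandas as pd
import pytest

from circlescope.circlecall import CircleCall
from circlescope.io_core import GenomicInterval
from circlescope.recurrence import (
    bin_circle_reads,
    classify_bins,
    ecdna_cooccurrence,
    make_bins,
    mark_positive,
    recurrence_fractions,
)

from conftest import make_read

SIZES = {"chr1": 1_000_000, "chrM": 16_569}


def call(chrom, start, end, classified=True):
    c = CircleCall(interval=GenomicInterval(chrom, start, end), n_split=2)
    c.classified = classified
    return c


class TestBinCircleReads:
    def test_cell_without_circles_has_zero_row(self):
        reads = {"c0": [make_read(read_id="r0")]}
        raw, cpm = bin_circle_reads(reads, {"c0": []}, make_bins(SIZES))
        assert raw.loc["c0"].sum() == 0

    def test_circle_inside_one_bin_collects_all_its_reads(self):
        bins = make_bins(SIZES)
        reads = {
            "c0": [make_read(start=150_000 + i * 10, end=150_150 + i * 10,
                             read_id=f"r{i}") for i in range(20)]
        }
        circles = {"c0": [call("chr1", 149_000, 160_000)]}
        raw, cpm = bin_circle_reads(reads, circles, bins)
        assert raw.loc["c0", "chr1:100000-200000"] == 20
        assert raw.loc["c0"].sum() == 20
        assert cpm.loc["c0", "chr1:100000-200000"] == pytest.approx(1e6)

    def test_straddling_read_assigned_by_start_bin(self):
        bins = make_bins(SIZES)
        reads = {"c0": [make_read(start=99_950, end=100_100, read_id="r0")]}
        circles = {"c0": [call("chr1", 99_000, 101_000)]}
        raw, _ = bin_circle_reads(reads, circles, bins)
        assert raw.loc["c0", "chr1:0-100000"] == 1
        assert raw.loc["c0", "chr1:100000-200000"] == 0

    def test_reads_outside_circles_do_not_count(self):
        bins = make_bins(SIZES)
        reads = {"c0": [make_read(start=500_000, end=500_150, read_id="r0")]}
        circles = {"c0": [call("chr1", 10_000, 12_000)]}
        raw, _ = bin_circle_reads(reads, circles, bins)
        assert raw.loc["c0"].sum() == 0


class TestMarkPositive:
    def test_flat_counts_are_never_positive(self):
        counts = pd.DataFrame(
            np.full((2, 20), 7.0),
            index=["c0", "c1"],
            columns=[f"chr1:{i}-{i+1}" for i in range(20)],
        )
        assert not mark_positive(counts).to_numpy().any()

    def test_hundredfold_bin_is_positive(self):
        values = np.full(30, 5.0)
        values[3] = 500.0
        counts = pd.DataFrame([values], index=["c0"],
                              columns=[f"chr1:{i}-{i+1}" for i in range(30)])
        out = mark_positive(counts)
        assert out.iloc[0, 3]
        assert out.iloc[0].sum() == 1

    def test_empty_cell_has_no_positives(self):
        counts = pd.DataFrame(np.zeros((1, 10)), index=["c0"],
                              columns=[f"chr1:{i}-{i+1}" for i in range(10)])
        assert not mark_positive(counts).to_numpy().any()

    def test_null_positive_rate_within_alpha(self):
        """Uniform Poisson counts: the per-cell positive-bin rate stays
        below the nominal 5% plus three binomial standard errors."""
        rng = np.random.default_rng(0)
        n_bins = 2_000
        counts = pd.DataFrame(
            rng.poisson(20.0, size=(10, n_bins)).astype(float),
            index=[f"c{i}" for i in range(10)],
            columns=[f"chr1:{i}-{i+1}" for i in range(n_bins)],
        )
        out = mark_positive(counts)
        rate = out.to_numpy().mean(axis=1)
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_bins)
        assert (rate <= bound).all()

    def test_sparse_cell_warns(self):
        counts = pd.DataFrame(
            [[3.0] + [0.0] * 19], index=["c0"],
            columns=[f"chr1:{i}-{i+1}" for i in range(20)],
        )
        with pytest.warns(UserWarning, match="unstable"):
            mark_positive(counts)


class TestClassifyBins:
    def test_precedence_ecdna_chrm_other(self):
        bins = [
            GenomicInterval("chr1", 0, 100_000),
            GenomicInterval("chrM", 0, 16_569),
            GenomicInterval("chr1", 500_000, 600_000),
        ]
        amplicons = [GenomicInterval("chr1", 50_000, 70_000, "MYCN")]
        assert classify_bins(bins, amplicons) == ["ecDNA", "chrM", "other"]

    def test_chrm_amplicon_overlap_prefers_ecdna(self):
        bins = [GenomicInterval("chrM", 0, 16_569)]
        assert classify_bins(bins, [GenomicInterval("chrM", 0, 100)]) == ["ecDNA"]


class TestRecurrenceFractions:
    def test_clonal_category_reaches_one_and_absent_zero(self):
        positive = pd.DataFrame(
            [[True, False], [True, False], [True, False]],
            index=["c0", "c1", "c2"],
            columns=["b0", "b1"],
        )
        fractions, per_bin = recurrence_fractions(positive, ["ecDNA", "chrM"])
        assert fractions["ecDNA"] == 1.0
        assert fractions["chrM"] == 0.0
        assert per_bin["b0"] == 1.0

    def test_private_bins_average_one_over_n(self):
        n = 8
        positive = pd.DataFrame(np.eye(n, dtype=bool),
                                index=[f"c{i}" for i in range(n)],
                                columns=[f"b{i}" for i in range(n)])
        _, per_bin = recurrence_fractions(positive, ["other"] * n)
        assert np.allclose(per_bin, 1.0 / n)

    def test_permutation_invariance_over_cells(self):
        rng = np.random.default_rng(1)
        positive = pd.DataFrame(rng.random((6, 5)) < 0.3,
                                index=[f"c{i}" for i in range(6)],
                                columns=[f"b{i}" for i in range(5)])
        cats = ["ecDNA", "chrM", "other", "other", "other"]
        f1, _ = recurrence_fractions(positive, cats)
        f2, _ = recurrence_fractions(positive.iloc[::-1], cats)
        assert (f1 == f2).all()

    def test_requires_at_least_one_cell(self):
        with pytest.raises(ValueError):
            recurrence_fractions(pd.DataFrame(columns=["b0"]), ["other"])


class TestCooccurrence:
    AMPS = {
        "MYCN": [GenomicInterval("chr1", 0, 10_000)],
        "CDK4": [GenomicInterval("chr1", 50_000, 60_000)],
        "MDM2": [GenomicInterval("chr1", 100_000, 110_000)],
    }

    def test_triple_positive_cell(self):
        circles = {"c0": [call("chr1", 1_000, 2_000), call("chr1", 52_000, 53_000),
                          call("chr1", 105_000, 106_000)]}
        presence, combos = ecdna_cooccurrence(circles, self.AMPS)
        assert presence.loc["c0"].all()
        assert combos["CDK4+MDM2+MYCN"] == 1

    def test_shared_region_counts_for_neither(self):
        amps = {
            "MYCN": [GenomicInterval("chr1", 0, 20_000)],
            "CDK4": [GenomicInterval("chr1", 15_000, 40_000)],
        }
        shared = [GenomicInterval("chr1", 15_000, 20_000)]
        circles = {"c0": [call("chr1", 16_000, 19_000)]}
        presence, combos = ecdna_cooccurrence(circles, amps, exclusions=shared)
        assert not presence.loc["c0"].any()
        assert combos["(none)"] == 1

    def test_no_circles_is_empty_combination(self):
        presence, combos = ecdna_cooccurrence({"c0": []}, self.AMPS)
        assert combos["(none)"] == 1

    def test_fully_excluded_amplicon_rejected(self):
        amps = {"MYCN": [GenomicInterval("chr1", 0, 1_000)]}
        with pytest.raises(ValueError, match="fully covered"):
            ecdna_cooccurrence({"c0": []}, amps,
                               exclusions=[GenomicInterval("chr1", 0, 1_000)])

    def test_row_sums_equal_presence_counts(self):
        rng = np.random.default_rng(0)
        circles = {}
        for i in range(12):
            cell = []
            for name, ivs in self.AMPS.items():
                if rng.random() < 0.5:
                    cell.append(call("chr1", ivs[0].start + 100, ivs[0].start + 900))
            circles[f"c{i:02d}"] = cell
        presence, combos = ecdna_cooccurrence(circles, self.AMPS)
        assert combos.sum() == len(circles)
        per_amp = presence.sum(axis=0)
        recomputed = {name: 0 for name in self.AMPS}
        for combo, count in combos.items():
            for name in self.AMPS:
                if name in combo:
                    recomputed[name] += count
        assert dict(per_amp) == recomputed
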