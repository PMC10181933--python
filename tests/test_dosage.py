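"""Copy-number estimation, trimmed background, SNP phasing and
small-circle grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from circlescope.circlecall import CircleCall
from circlescope.dosage import (
    correlate_cn_expression,
    estimate_relative_cn,
    phase_snps,
    small_circle_content_groups,
    trimmed_mean,
)
from circlescope.io_core import GenomicInterval


def _genes(n_background=40, amp_interval=None):
    genes = []
    if amp_interval is not None:
        genes.append(GenomicInterval(amp_interval.chrom, amp_interval.start,
                                     amp_interval.end, "AMP"))
    for i in range(n_background):
        start = 1_000_000 + i * 10_000
        genes.append(GenomicInterval("chr1", start, start + 5_000, f"g{i}"))
    return genes


class TestTrimmedMean:
    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(20, 400))
            values = rng.lognormal(0, 1, size=n)
            k = int(n * 0.05)
            expected = np.sort(values)[k : n - k].mean()
            assert trimmed_mean(values) == expected

    def test_winsorized_variant_clamps(self):
        values = np.array([1.0] * 18 + [0.0, 1000.0] + [1.0] * 20)
        k = int(len(values) * 0.05)
        arr = np.sort(values)
        expected = np.clip(arr, arr[k], arr[len(values) - k - 1]).mean()
        assert trimmed_mean(values, winsorize=True) == expected

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=20, max_size=100))
    def test_bounded_by_data_range(self, values):
        tm = trimmed_mean(values)
        assert min(values) <= tm <= max(values)


class TestEstimateRelativeCN:
    AMP = GenomicInterval("chr1", 10_000, 20_000)

    def _coverage(self, amp_cov, background_cov=1.0, genes=None):
        genes = genes or _genes(amp_interval=self.AMP)
        cov = {g.name: background_cov for g in genes}
        cov["AMP"] = amp_cov
        return pd.Series(cov), genes

    def test_sixtyfour_fold_gives_log2_six(self):
        cov, genes = self._coverage(64.0)
        est = estimate_relative_cn(cov, genes, None, {"A": [self.AMP]})
        assert est[0].log2_ratio == pytest.approx(6.0)

    def test_uniform_coverage_gives_zero(self):
        cov, genes = self._coverage(1.0)
        est = estimate_relative_cn(cov, genes, None, {"A": [self.AMP]})
        assert est[0].log2_ratio == pytest.approx(0.0)

    def test_extreme_background_outliers_are_trimmed_away(self):
        genes = _genes(n_background=60, amp_interval=self.AMP)
        cov, _ = self._coverage(64.0, genes=genes)
        clean = estimate_relative_cn(cov, genes, None, {"A": [self.AMP]})[0].log2_ratio
        dirty = cov.copy()
        for name in [f"g{i}" for i in range(2)]:  # ~3% of 61 genes
            dirty[name] = 1000.0
        polluted = estimate_relative_cn(dirty, genes, None, {"A": [self.AMP]})[0].log2_ratio
        assert abs(polluted - clean) / abs(clean) < 0.01

    def test_scaling_invariance(self):
        cov, genes = self._coverage(16.0, 0.5)
        a = estimate_relative_cn(cov, genes, None, {"A": [self.AMP]})[0].log2_ratio
        b = estimate_relative_cn(cov * 37.0, genes, None, {"A": [self.AMP]})[0].log2_ratio
        assert a == pytest.approx(b)

    def test_cell_circle_calls_extend_amplicon_genes(self):
        genes = _genes(amp_interval=self.AMP)
        cov, _ = self._coverage(64.0)
        cov["g0"] = 64.0  # this gene is covered by a cell circle call
        circle = CircleCall(interval=GenomicInterval("chr1", 1_000_000, 1_006_000))
        circle.classified = True
        est = estimate_relative_cn(cov, genes, [circle], {"A": [self.AMP]})
        # g0 must have left the background, so the ratio is unchanged
        assert est[0].log2_ratio == pytest.approx(6.0)

    def test_too_few_background_genes_rejected(self):
        genes = _genes(n_background=5, amp_interval=self.AMP)
        cov = pd.Series({g.name: 1.0 for g in genes})
        with pytest.raises(ValueError, match="non-amplicon genes"):
            estimate_relative_cn(cov, genes, None, {"A": [self.AMP]})

    def test_zero_background_flagged(self):
        cov, genes = self._coverage(10.0, background_cov=0.0)
        with pytest.warns(UserWarning, match="zero background"):
            est = estimate_relative_cn(cov, genes, None, {"A": [self.AMP]})
        assert np.isnan(est[0].log2_ratio)


class TestCorrelation:
    def test_perfectly_linear_gives_r_one(self):
        cn = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        report = correlate_cn_expression(cn, 2 * cn)
        assert report["r"] == pytest.approx(1.0)
        assert report["slope"] == pytest.approx(2.0)

    def test_zero_variance_flagged(self):
        cn = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        with pytest.warns(UserWarning):
            report = correlate_cn_expression(cn, pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert np.isnan(report["r"])

    def test_requires_three_shared_cells(self):
        cn = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(ValueError):
            correlate_cn_expression(cn, cn)


class TestPhaseSnps:
    def _bulk(self, alt, depth):
        return pd.DataFrame([{"chrom": "chr1", "pos": 100, "alt_count": alt,
                              "depth": depth}])

    def test_ninety_of_hundred_is_gained(self):
        phased, _ = phase_snps(self._bulk(90, 100))
        assert phased[0].allele_assignment == "gained"
        assert phased[0].p_value < 1e-10

    def test_fiftytwo_of_hundred_is_unassigned(self):
        phased, _ = phase_snps(self._bulk(52, 100))
        assert phased[0].allele_assignment == "unassigned"
        assert phased[0].p_value == pytest.approx(0.764, abs=0.01)

    def test_low_baf_is_not_gained(self):
        phased, _ = phase_snps(self._bulk(10, 100))
        assert phased[0].allele_assignment == "not_gained"

    def test_zero_depth_unassigned(self):
        phased, _ = phase_snps(self._bulk(0, 0))
        assert phased[0].allele_assignment == "unassigned"

    def test_monoallelic_cells_sit_on_the_assigned_side(self):
        """Cells amplifying one allele keep per-cell BAF above 0.5 at
        SNPs assigned 'gained' from bulk."""
        rng = np.random.default_rng(0)
        cn = 10
        baf = (1 + cn) / (2 + cn)
        bulk = pd.DataFrame([
            {"chrom": "chr1", "pos": p, "alt_count": int(rng.binomial(500, baf)),
             "depth": 500}
            for p in range(5)
        ])
        rows = []
        for cell in range(40):
            for p in range(5):
                d = 60
                rows.append({"cell_id": f"c{cell:02d}", "chrom": "chr1", "pos": p,
                             "alt_count": int(rng.binomial(d, baf)), "depth": d})
        phased, baf_matrix = phase_snps(bulk, pd.DataFrame(rows))
        assert all(s.allele_assignment == "gained" for s in phased)
        values = baf_matrix.to_numpy()
        assert (values > 0.5).mean() >= 0.95


class TestContentGroups:
    @staticmethod
    def _cells(contents):
        circles = {}
        for i, content in enumerate(contents):
            n_small = int(round(content * 10))
            cell = []
            for j in range(n_small):
                c = CircleCall(interval=GenomicInterval("chr1", j * 10_000, j * 10_000 + 1_000))
                c.classified = True
                cell.append(c)
            for j in range(10 - n_small):
                c = CircleCall(interval=GenomicInterval("chr1", 500_000 + j * 20_000,
                                                        500_000 + j * 20_000 + 10_000))
                c.classified = True
                cell.append(c)
            circles[f"c{i:02d}"] = cell
        return circles

    def test_forty_forty_twenty_split(self):
        table = small_circle_content_groups(self._cells([i / 10 for i in range(10)]))
        assert (table["group"] == "low").sum() == 4
        assert (table["group"] == "high").sum() == 4
        assert (table["group"] == "mid").sum() == 2
        assert set(table[table["group"] == "low"]["cell_id"]) == {"c00", "c01", "c02", "c03"}

    def test_ties_break_by_cell_id(self):
        table = small_circle_content_groups(self._cells([0.5] * 5))
        assert list(table.sort_values("cell_id")["group"]) == [
            "low", "low", "mid", "high", "high",
        ]

    def test_all_small_circles_give_content_one(self):
        table = small_circle_content_groups(self._cells([1.0]))
        assert table["content"].iloc[0] == 1.0

    def test_zero_circle_cell_excluded_with_warning(self):
        circles = self._cells([0.5])
        circles["empty"] = []
        with pytest.warns(UserWarning, match="no circles"):
            table = small_circle_content_groups(circles)
        assert "empty" not in set(table["cell_id"])
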