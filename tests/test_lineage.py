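"""mtDNA variant calling, consensus filtering, AF matrix and clustering."""

import numpy as np
import pandas as pd
import pytest

from circlescope import lineage, sim
from circlescope.lineage import (
    build_af_matrix,
    cluster_cells,
    consensus_filter,
    filter_af_matrix,
    pileup_call,
    to_newick,
)


def pileup(rows):
    """rows: (pos, ref, A, C, G, T)"""
    return pd.DataFrame(rows, columns=["pos", "ref", "A", "C", "G", "T"])


class TestPileupCall:
    def test_threshold_arithmetic(self):
        table = pileup([(1, "A", 95, 5, 0, 0)])  # 5/100 = 5% with 5 alt reads
        calls = pileup_call(table, "c0")
        assert len(calls) == 1 and calls[0].alt == "C" and calls[0].af == 0.05

    def test_low_fraction_not_called(self):
        table = pileup([(1, "A", 998, 2, 0, 0)])  # 0.2% and only 2 reads
        assert pileup_call(table, "c0") == []

    def test_all_reference_position_silent(self):
        assert pileup_call(pileup([(1, "G", 0, 0, 100, 0)]), "c0") == []

    def test_zero_depth_no_call(self):
        assert pileup_call(pileup([(1, "A", 0, 0, 0, 0)]), "c0") == []


class TestConsensusFilter:
    @staticmethod
    def _call(cell, pos, alt, tag):
        return lineage.VariantCall(cell, pos, "A", alt, 0.2, 20, 100, tag)

    def test_single_cell_support_fails_both_steps(self):
        a = [self._call("c0", 1, "T", "A")]
        b = [self._call(f"c{i}", 1, "T", "B") for i in range(5)]
        assert consensus_filter(a, b) == set()

    def test_three_cells_by_both_is_retained(self):
        a = [self._call(f"c{i}", 1, "T", "A") for i in range(3)]
        b = [self._call(f"c{i}", 1, "T", "B") for i in range(3)]
        assert consensus_filter(a, b) == {(1, "T")}

    def test_empty_call_sets(self):
        assert consensus_filter([], []) == set()


class TestAFMatrix:
    def test_equation_and_missing_entries(self):
        pileups = {
            "c0": pileup([(1, "A", 160, 40, 0, 0)]),  # AF 40/200 = 0.2
            "c1": pileup([(1, "A", 0, 0, 0, 0)]),     # depth 0 -> missing
        }
        m = build_af_matrix(pileups, {(1, "C")})
        assert m.loc["c0", "1:C"] == pytest.approx(0.2)
        assert np.isnan(m.loc["c1", "1:C"])

    def test_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(0)
        pileups = {}
        for i in range(6):
            rows = []
            for pos in range(5):
                counts = rng.integers(0, 50, size=4)
                rows.append((pos, "A", *counts))
            pileups[f"c{i}"] = pileup(rows)
        variants = {(p, b) for p in range(5) for b in "CGT"}
        m = build_af_matrix(pileups, variants)
        for cell, table in pileups.items():
            for pos, alt in variants:
                row = table.set_index("pos").loc[pos]
                depth = row[["A", "C", "G", "T"]].sum()
                expected = row[alt] / depth if depth else np.nan
                got = m.loc[cell, f"{pos}:{alt}"]
                assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)

    def test_empty_variant_set_rejected(self):
        with pytest.raises(ValueError):
            build_af_matrix({}, set())


class TestFilterAFMatrix:
    @staticmethod
    def _matrix(data, cells=None):
        cells = cells or [f"c{i}" for i in range(len(data))]
        return pd.DataFrame(data, index=cells,
                            columns=[f"{j}:T" for j in range(len(data[0]))])

    def test_low_max_af_column_dropped(self):
        m = self._matrix([[0.04, 0.25, 0.28, 0.22], [0.03, 0.27, 0.24, 0.26],
                          [0.02, 0.26, 0.29, 0.25]])
        filtered, log = filter_af_matrix(m, min_cell_variants=2)
        assert "0:T" not in filtered.columns

    def test_high_mean_af_column_dropped(self):
        m = self._matrix([[0.5, 0.2, 0.25, 0.22], [0.55, 0.22, 0.21, 0.2],
                          [0.45, 0.18, 0.2, 0.24]])
        filtered, _ = filter_af_matrix(m, min_cell_variants=2)
        assert "0:T" not in filtered.columns

    def test_sparse_cells_dropped(self):
        m = self._matrix([[0.25, 0.25, 0.25], [0.25, 0.25, 0.25], [0.0, 0.0, 0.1]])
        filtered, _ = filter_af_matrix(m)
        assert "c2" not in filtered.index

    def test_clean_two_clone_matrix_untouched_and_idempotent(self):
        rng = np.random.default_rng(1)
        a = np.clip(rng.normal(0.4, 0.03, size=(10, 3)), 0, 1)
        b = np.zeros((10, 3))
        top = np.hstack([a, b])
        bottom = np.hstack([b, a])
        m = pd.DataFrame(np.vstack([top, bottom]),
                         index=[f"c{i:02d}" for i in range(20)],
                         columns=[f"{j}:T" for j in range(6)])
        filtered, log = filter_af_matrix(m)
        assert filtered.shape == m.shape
        again, _ = filter_af_matrix(filtered)
        pd.testing.assert_frame_equal(filtered, again)

    def test_everything_filtered_is_an_error(self):
        m = self._matrix([[0.01, 0.02], [0.02, 0.01]])
        with pytest.raises(ValueError, match="review thresholds"):
            filter_af_matrix(m)


class TestClusterCells:
    @staticmethod
    def _two_clones(n=20, af=0.4, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        m = rng.normal(0, noise, size=(n, 6)).clip(0, 1)
        m[:half, :3] += af
        m[half:, 3:] += af
        return pd.DataFrame(m.clip(0, 1), index=[f"c{i:02d}" for i in range(n)],
                            columns=[f"{j}:T" for j in range(6)])

    def test_disjoint_clones_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        m = self._two_clones(noise=0.02)
        link, labels, ids, _ = cluster_cells(m, n_clusters=2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels.loc[ids]) == 1.0

    def test_pure_noise_has_no_stable_split(self):
        from scipy.spatial.distance import pdist
        from scipy.cluster import hierarchy

        rng = np.random.default_rng(2)
        silhouettes = []
        for rep in range(5):
            m = pd.DataFrame(rng.uniform(0, 0.01, size=(30, 6)),
                             index=[f"c{i:02d}" for i in range(30)],
                             columns=[f"{j}:T" for j in range(6)])
            link, labels, ids, _ = cluster_cells(m, n_clusters=2)
            from sklearn.metrics import silhouette_score

            silhouettes.append(silhouette_score(m.loc[ids], labels.loc[ids]))
        assert np.mean(silhouettes) < 0.25

    def test_duplicated_cells_merge_first(self):
        m = self._two_clones(noise=0.05, seed=3)
        m.loc["c00"] = m.loc["c01"]
        link, _, ids, _ = cluster_cells(m)
        first = link[0]
        merged = {ids[int(first[0])], ids[int(first[1])]}
        assert merged == {"c00", "c01"} and first[2] == 0.0

    def test_row_permutation_invariance(self):
        m = self._two_clones(noise=0.02, seed=4)
        l1, lab1, ids1, _ = cluster_cells(m, n_clusters=2)
        shuffled = m.sample(frac=1.0, random_state=7)
        l2, lab2, ids2, _ = cluster_cells(shuffled, n_clusters=2)
        assert ids1 == ids2
        assert np.allclose(l1, l2)

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError):
            cluster_cells(self._two_clones().iloc[:1])

    def test_newick_export_parses(self):
        import dendropy

        m = self._two_clones(noise=0.02, seed=5)
        link, _, ids, _ = cluster_cells(m)
        newick = to_newick(link, ids)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert len(tree.leaf_nodes()) == len(ids)


class TestEndToEndCloneRecovery:
    def test_generator_to_clusters(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = sim.SimConfig(
            chrom_sizes={"chr1": 10_000, "chrM": 16_569},
            n_cells=24,
            clone_spec=[
                sim.CloneSpec("A", 0.5, mt_variants=[(10, "T", 0.4), (20, "G", 0.4),
                                                     (30, "C", 0.4)]),
                sim.CloneSpec("B", 0.5, mt_variants=[(40, "A", 0.4), (50, "T", 0.4),
                                                     (60, "G", 0.4)]),
            ],
            seed=6,
        )
        pileups = sim.simulate_mt_pileups(cfg)
        calls_a = [c for cell, t in sorted(pileups.items())
                   for c in pileup_call(t, cell, 0.01, 3, "strict")]
        calls_b = [c for cell, t in sorted(pileups.items())
                   for c in pileup_call(t, cell, 0.005, 2, "lenient")]
        retained = consensus_filter(calls_a, calls_b)
        m, _ = filter_af_matrix(build_af_matrix(pileups, retained))
        link, labels, ids, _ = cluster_cells(m, n_clusters=2)
        assignment = sim.assign_clones(cfg)
        truth = [assignment[c].name for c in ids]
        assert adjusted_rand_score(truth, labels.loc[ids]) == 1.0
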