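"""Generator contracts: determinism, truth structure, read evidence,
expression coupling and pileup composition."""

import numpy as np
import pandas as pd
import pytest

from circlescope import sim
from circlescope.io_core import GenomicInterval, parse_alignments


def test_zero_length_chromosome_rejected():
    with pytest.raises(ValueError, match="zero-length"):
        sim.SimConfig(chrom_sizes={"chr1": 0})


def test_clone_fractions_must_sum_to_one():
    with pytest.raises(ValueError, match="fractions"):
        sim.SimConfig(clone_spec=[sim.CloneSpec("a", 0.6), sim.CloneSpec("b", 0.6)])


def test_genome_lengths_and_determinism(tmp_path):
    cfg = sim.SimConfig(chrom_sizes={"chr1": 10_000, "chrM": 2_000}, seed=1)
    g1 = sim.make_genome(cfg, tmp_path / "a.fa")
    g2 = sim.make_genome(cfg, tmp_path / "b.fa")
    assert {k: len(v) for k, v in g1.items()} == {"chr1": 10_000, "chrM": 2_000}
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert sim.PMEI_MOTIF in g1["chrM"]


def test_pmei_flag_implies_motif_in_sequence(small_sim):
    cfg, genome, truths = small_sim
    flagged = [t for t in truths if t.contains_pmei_site]
    assert flagged, "expected at least chrM to carry the motif"
    for t in flagged:
        assert any(
            sim.PMEI_MOTIF in genome[f.chrom][f.start : f.end] for f in t.fragments
        )


def test_rate_zero_leaves_only_ecdna_and_chrm():
    frag = GenomicInterval("chr1", 1_000, 5_000)
    cfg = sim.SimConfig(
        chrom_sizes={"chr1": 50_000, "chrM": 2_000},
        n_cells=4,
        small_circle_rate=0,
        ecdna_spec=[sim.AmpliconSpec("A", [frag], ("fixed", 3))],
        clone_spec=[sim.CloneSpec("c", 1.0, ["A"])],
        seed=0,
    )
    truths = sim.plant_truth(cfg)
    assert {t.origin for t in truths} == {"ecdna", "chrM"}
    for cell in cfg.cell_ids():
        assert sum(t.cell_id == cell for t in truths) == 2


def test_amplicon_outside_chromosome_rejected():
    frag = GenomicInterval("chr1", 1_000, 500_000)
    with pytest.raises(ValueError):
        sim.SimConfig(
            chrom_sizes={"chr1": 50_000},
            ecdna_spec=[sim.AmpliconSpec("A", [frag])],
        )


def test_small_circle_counts_are_poisson():
    cfg = sim.SimConfig(
        chrom_sizes={"chr1": 5_000_000},
        n_cells=200,
        small_circle_rate=20,
        seed=0,
    )
    truths = sim.plant_truth(cfg)
    counts = pd.Series([t.cell_id for t in truths if t.origin == "small"]).value_counts()
    counts = counts.reindex(cfg.cell_ids(), fill_value=0)
    se = np.sqrt(20 / 200)
    assert abs(counts.mean() - 20) < 3 * se


def test_truth_conservation_without_background(small_sim, tmp_path):
    """With linear retention at its floor, every emitted read lies on a
    truth circle (within a read length of its fragments)."""
    cfg, genome, truths = small_sim
    cfg2 = sim.SimConfig(
        **{
            **cfg.__dict__,
            "background_depth": 0.0,
            "n_cells": 2,
            "seed": 11,
        }
    )
    truths2 = sim.plant_truth(cfg2, genome)
    paths = sim.simulate_reads(truths2, cfg2, tmp_path)
    for cell, path in paths.items():
        cell_truths = [t for t in truths2 if t.cell_id == cell]
        for r in parse_alignments(path, cell_id=cell):
            ok = any(
                f.chrom == r.chrom
                and r.start >= f.start - cfg2.read_length
                and r.end <= f.end + cfg2.read_length
                for t in cell_truths
                for f in t.fragments
            )
            assert ok, f"read {r.read_id} at {r.chrom}:{r.start} off-truth"


def test_junction_fragment_yields_split_pair(tmp_path):
    """A fragment crossing the circle junction emits two alignments with
    the same read id and complementary clipping."""
    circle = GenomicInterval("chr1", 20_000, 30_000)
    cfg = sim.SimConfig(
        chrom_sizes={"chr1": 100_000},
        n_cells=1,
        small_circle_rate=0,
        ecdna_spec=[sim.AmpliconSpec("A", [circle], ("fixed", 1))],
        clone_spec=[sim.CloneSpec("c", 1.0, ["A"])],
        condition="none",
        circle_depth_per_copy=1.0,
        background_depth=0.0,
        seed=0,
    )
    truths = [t for t in sim.plant_truth(cfg) if t.origin == "ecdna"]
    paths = sim.simulate_reads(truths, cfg, tmp_path)
    reads = list(parse_alignments(paths["cell_0000"]))
    split = {}
    for r in reads:
        if r.is_split:
            split.setdefault(r.read_id, []).append(r)
    assert split, "no junction-crossing fragments emitted"
    for rid, pieces in split.items():
        assert len(pieces) == 2
        sides = sorted(p.start for p in pieces)
        assert abs(sides[0] - circle.start) <= cfg.read_length
        assert abs(sides[1] - (circle.end - cfg.read_length)) <= cfg.read_length
        total = sum(len(p) for p in pieces)
        assert total == cfg.read_length  # complementary clipping


def test_sam_output_is_deterministic(tmp_path, small_sim):
    cfg, genome, truths = small_sim
    a = sim.simulate_reads(truths, cfg, tmp_path / "a", cells=["cell_0000"])
    b = sim.simulate_reads(truths, cfg, tmp_path / "b", cells=["cell_0000"])
    assert a["cell_0000"].read_bytes() == b["cell_0000"].read_bytes()


class TestExpression:
    @staticmethod
    def _setup(coupling, dispersion=0.01, cn=("fixed", 10)):
        frag = GenomicInterval("chr1", 10_000, 20_000)
        cfg = sim.SimConfig(
            chrom_sizes={"chr1": 200_000},
            n_cells=40,
            small_circle_rate=0,
            ecdna_spec=[sim.AmpliconSpec("AMP", [frag], cn)],
            clone_spec=[sim.CloneSpec("c", 1.0, ["AMP"])],
            n_genes=30,
            expression_coupling=coupling,
            expression_dispersion=dispersion,
            seed=3,
        )
        truths = sim.plant_truth(cfg)
        genes = sim.make_genes(cfg)
        return cfg, truths, genes

    def test_zero_coupling_leaves_amplicon_genes_at_baseline(self):
        cfg, truths, genes = self._setup(coupling=0.0)
        counts = sim.simulate_expression(truths, genes, cfg)
        cfg1, truths1, _ = self._setup(coupling=1.0)
        counts1 = sim.simulate_expression(truths1, genes, cfg1)
        # with coupling the amplicon gene moves ~10x; without it stays put
        assert counts1.loc["AMP"].mean() > 4 * counts.loc["AMP"].mean()

    def test_copy_number_drives_counts(self):
        cfg, truths, genes = self._setup(coupling=1.0, cn=("lognormal", 8, 0.8))
        counts = sim.simulate_expression(truths, genes, cfg)
        cn = {t.cell_id: t.copy_number for t in truths if t.origin == "ecdna"}
        cells = [c for c in counts.columns if c in cn]
        r = np.corrcoef([cn[c] for c in cells], counts.loc["AMP", cells])[0, 1]
        assert r > 0.95

    def test_absent_amplicon_stays_at_baseline(self):
        cfg, truths, genes = self._setup(coupling=1.0)
        without = [t for t in truths if t.origin != "ecdna"]
        counts_without = sim.simulate_expression(without, genes, cfg)
        cfg0, truths0, _ = self._setup(coupling=0.0)
        baseline = sim.simulate_expression(truths0, genes, cfg0)
        ratio = counts_without.loc["AMP"].mean() / baseline.loc["AMP"].mean()
        assert 0.7 < ratio < 1.4

    def test_zero_length_gene_rejected(self):
        cfg, truths, genes = self._setup(coupling=1.0)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)  # cannot even be constructed


class TestMtPileups:
    def test_zero_error_full_heteroplasmy_gives_af_one(self):
        cfg = sim.SimConfig(
            chrom_sizes={"chr1": 10_000, "chrM": 16_569},
            n_cells=2,
            clone_spec=[sim.CloneSpec("c", 1.0, mt_variants=[(100, "T", 1.0)])],
            mt_error_rate=0.0,
            seed=0,
        )
        pileups = sim.simulate_mt_pileups(cfg)
        for table in pileups.values():
            row = table.set_index("pos").loc[100]
            depth = row[["A", "C", "G", "T"]].sum()
            assert depth > 0 and row["T"] == depth

    def test_heteroplasmy_fraction_outside_unit_interval_rejected(self):
        cfg = sim.SimConfig(
            chrom_sizes={"chrM": 16_569, "chr1": 1_000},
            clone_spec=[sim.CloneSpec("c", 1.0, mt_variants=[(5, "A", 1.5)])],
        )
        with pytest.raises(ValueError, match="heteroplasmy"):
            sim.simulate_mt_pileups(cfg)

    def test_zero_depth_position_emitted_with_zero_counts(self):
        cfg = sim.SimConfig(
            chrom_sizes={"chr1": 1_000, "chrM": 16_569},
            n_cells=1,
            clone_spec=[sim.CloneSpec("c", 1.0, mt_variants=[(10, "T", 0.4)])],
            mt_pileup_depth=0,
            seed=0,
        )
        table = sim.simulate_mt_pileups(cfg)["cell_0000"]
        assert (table[["A", "C", "G", "T"]].sum(axis=1) == 0).all()


def test_clone_assignment_matches_fractions():
    cfg = sim.SimConfig(
        chrom_sizes={"chr1": 10_000, "chrM": 16_569},
        n_cells=10,
        clone_spec=[sim.CloneSpec("a", 0.7), sim.CloneSpec("b", 0.3)],
        seed=0,
    )
    assignment = sim.assign_clones(cfg)
    names = pd.Series([c.name for c in assignment.values()]).value_counts()
    assert names["a"] == 7 and names["b"] == 3
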