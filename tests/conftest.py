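import numpy as np
import pytest

from circlescope.io_core import GenomicInterval, ReadRecord


def make_read(
    chrom="chr1",
    start=0,
    end=150,
    read_id="r0",
    cell_id="cell",
    mapq=60,
    is_split=False,
    orientation="inward",
    is_supplementary=False,
):
    return ReadRecord(
        cell_id=cell_id,
        read_id=read_id,
        chrom=chrom,
        start=start,
        end=end,
        mapq=mapq,
        is_split=is_split,
        is_supplementary=is_supplementary,
        orientation=orientation,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 3-cell simulation shared by generator/caller tests."""
    from circlescope import sim

    cfg = sim.SimConfig(
        chrom_sizes={"chr1": 500_000, "chrM": 16_569},
        n_cells=3,
        small_circle_rate=8,
        small_circle_size_dist={"kind": "loguniform", "min": 500, "max": 30_000},
        condition="none",
        seed=1,
        circle_depth_per_copy=20.0,
        mt_copy_number=2,
    )
    genome = sim.make_genome(cfg)
    truths = sim.plant_truth(cfg, genome)
    return cfg, genome, truths


@pytest.fixture(scope="session")
def small_sim_reads(small_sim, tmp_path_factory):
    from circlescope import sim
    from circlescope.io_core import parse_alignments

    cfg, genome, truths = small_sim
    out = tmp_path_factory.mktemp("sams")
    paths = sim.simulate_reads(truths, cfg, out)
    reads = {cell: list(parse_alignments(p, cell_id=cell)) for cell, p in paths.items()}
    return cfg, truths, reads, paths


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
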