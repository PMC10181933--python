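"""Synthetic single-cell Circle-seq data generator.

Emulates the statistical structure that exonuclease-enriched circular-DNA
sequencing produces, so every downstream stage can be exercised offline:

* a toy genome (FASTA) with a circular mitochondrial chromosome;
* per-cell circle truth sets -- Poisson-distributed private small circles
  with log-normal sizes, clone-shared multi-fragment ecDNA amplicons with
  per-cell copy numbers, and mtDNA in every cell;
* aligned read records (SAM text) in which fragments spanning a circle
  junction yield split alignments (SA-tagged, complementary clipping) and
  outward-facing pairs -- exactly the two evidence classes the circle
  caller consumes -- plus uniform linear background;
* digestion conditions modelled as per-molecule retention probabilities
  for circular vs. linear DNA (no digestion / 1-day exo / 5-day exo /
  PmeI + 5-day exo, where circles carrying the PmeI motif GTTTAAAC are
  linearized and degraded);
* dosage-coupled expression counts, mtDNA allele-count pileups with
  clonal heteroplasmy, heterozygous-SNP allele counts over amplicons,
  and a smooth chromatin signal track with peak calls.

Reads are emitted directly as aligned records: alignment itself is out of
scope here and mapping noise is a configurable mismap rate.  Coordinates
are 0-based half-open internally; SAM output is 1-based per the standard.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .io_core import GenomicInterval, write_bed, write_chrom_sizes

__all__ = [
    "SimConfig",
    "CloneSpec",
    "AmpliconSpec",
    "CircleTruth",
    "make_genome",
    "plant_truth",
    "simulate_reads",
    "make_genes",
    "simulate_expression",
    "simulate_mt_pileups",
    "simulate_snp_counts",
    "simulate_chromatin_track",
    "write_truth_tsv",
]

PMEI_MOTIF = "GTTTAAAC"
_BASES = np.frombuffer(b"ACGT", dtype="S1")

# condition -> (circular retention, linear retention).  Digestion is a
# per-molecule survival probability, not kinetics: only the relative
# enrichment outcome matters downstream.  The 5-day exo ratio (425x) is
# of the order of the mtDNA depletion observed when PmeI linearizes the
# circles first.
DEFAULT_ENRICHMENT = {
    "none": (1.0, 1.0),
    "exo1d": (0.90, 0.05),
    "exo5d": (0.85, 0.002),
    "pmei_exo5d": (0.85, 0.002),
}

# rng stream codes, one per generator op, so ops are independently
# reproducible for a fixed config seed regardless of call order
_S_GENOME, _S_TRUTH, _S_READS, _S_EXPR, _S_MT, _S_SNP, _S_TRACK, _S_GENES = range(8)


@dataclass
class AmpliconSpec:
    """A named multi-fragment ecDNA amplicon.

    ``fragments`` is the ordered list of genomic segments on the circle;
    consecutive fragments (and the last-to-first wrap) are junctions.
    ``cn_dist`` draws the per-cell copy number: ``("fixed", k)``,
    ``("poisson", mean)`` or ``("lognormal", median, sigma)``.
    """

    name: str
    fragments: list[GenomicInterval]
    cn_dist: tuple = ("lognormal", 20.0, 0.5)

    def draw_cn(self, rng: np.random.Generator) -> int:
        kind = self.cn_dist[0]
        if kind == "fixed":
            return int(self.cn_dist[1])
        if kind == "poisson":
            return int(rng.poisson(self.cn_dist[1]))
        if kind == "lognormal":
            return max(1, int(round(rng.lognormal(np.log(self.cn_dist[1]), self.cn_dist[2]))))
        raise ValueError(f"unknown copy-number distribution {kind!r}")


@dataclass
class CloneSpec:
    """A clone: population fraction, which amplicons it carries, and its
    set of heteroplasmic mtDNA variants ``(position, alt, fraction)``."""

    name: str
    fraction: float
    amplicons: list[str] = field(default_factory=list)
    mt_variants: list[tuple[int, str, float]] = field(default_factory=list)


@dataclass
class CircleTruth:
    """One planted circle in one cell."""

    cell_id: str
    fragments: list[GenomicInterval]
    copy_number: int = 1
    contains_pmei_site: bool = False
    origin: str = "small"  # small | ecdna | chrM
    name: str = ""

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("circle truth needs at least one fragment")
        if self.copy_number < 1:
            raise ValueError("copy number must be >= 1")

    @property
    def length(self) -> int:
        return sum(len(f) for f in self.fragments)


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``small_circle_rate`` defaults to 700 circles per cell (the reported
    per-cell median is 702); sizes are log-normal around a 2-kb median
    with an optional second 20-kb mode capturing the observed bimodality.
    Desk-scale analyses override ``n_cells``/``chrom_sizes``/``rate``.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chrM": 16_569}
    )
    n_cells: int = 25
    clone_spec: list[CloneSpec] = field(
        default_factory=lambda: [CloneSpec("clone1", 1.0)]
    )
    ecdna_spec: list[AmpliconSpec] = field(default_factory=list)
    small_circle_rate: float = 700.0
    small_circle_size_dist: dict = field(
        default_factory=lambda: {
            "kind": "lognormal",
            "median": 2_000.0,
            "sigma": 0.8,
            "second_mode_median": 20_000.0,
            "second_mode_weight": 0.15,
            "min": 150,
        }
    )
    condition: str = "exo5d"
    enrichment_factors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENRICHMENT)
    )
    read_length: int = 150
    mean_insert: int = 500
    insert_sd: float = 50.0
    seed: int = 0
    # depth model: circle coverage = circle_depth_per_copy * CN * retention,
    # linear background coverage = background_depth * linear retention; at
    # the defaults a single-copy circle matches the linear genome per copy
    # and all enrichment comes from the digestion retention ratio.
    circle_depth_per_copy: float = 1.0
    background_depth: float = 1.0
    mt_copy_number: int = 100
    min_junction_fragments: int = 2
    mismap_rate: float = 0.0
    min_separation: int = 1_000  # between small circles within a cell
    # expression
    n_genes: int = 200
    expression_coupling: float = 1.0
    expression_dispersion: float = 0.1
    baseline_mean: float = 50.0
    # mtDNA pileups
    mt_pileup_depth: int = 100
    mt_error_rate: float = 0.002
    n_noise_positions: int = 50
    # SNP phasing inputs
    snps_per_amplicon: int = 8
    snp_bulk_depth: int = 200
    snp_cell_depth: int = 40

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom!r}")
        total = sum(c.fraction for c in self.clone_spec)
        if self.clone_spec and abs(total - 1.0) > 1e-6:
            raise ValueError(f"clone fractions sum to {total}, expected 1")
        for cond, (circ, lin) in self.enrichment_factors.items():
            if not (0 < circ <= 1 and 0 < lin <= 1):
                raise ValueError(f"retention factors for {cond!r} must be in (0, 1]")
        if self.condition not in self.enrichment_factors:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.read_length >= self.mean_insert:
            raise ValueError("read_length must be < mean_insert")
        for amp in self.ecdna_spec:
            for frag in amp.fragments:
                frag.validate_against(self.chrom_sizes)
        for clone in self.clone_spec:
            known = {a.name for a in self.ecdna_spec}
            missing = set(clone.amplicons) - known
            if missing:
                raise ValueError(f"clone {clone.name!r} references unknown amplicons {missing}")

    def retention(self) -> tuple[float, float]:
        return self.enrichment_factors[self.condition]

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *extra])

    def cell_ids(self) -> list[str]:
        width = max(4, len(str(self.n_cells - 1)))
        return [f"cell_{i:0{width}d}" for i in range(self.n_cells)]


# ---------------------------------------------------------------------------
# genome


def make_genome(config: SimConfig, fasta_path=None) -> dict[str, str]:
    """Random genome with a PmeI site planted on chrM (mtDNA carries the
    motif: the endonuclease control must deplete it).  Deterministic for
    a fixed seed; optionally written as FASTA (plus .fai-compatible text).
    """
    rng = config.rng(_S_GENOME)
    genome: dict[str, str] = {}
    for chrom, length in config.chrom_sizes.items():
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        genome[chrom] = seq
    if "chrM" in genome and PMEI_MOTIF not in genome["chrM"]:
        seq = genome["chrM"]
        pos = len(seq) // 2
        genome["chrM"] = seq[:pos] + PMEI_MOTIF + seq[pos + len(PMEI_MOTIF):]
    if fasta_path is not None:
        with open(fasta_path, "w") as handle:
            for chrom, seq in genome.items():
                handle.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    handle.write(seq[i : i + 80] + "\n")
    return genome


def _contains_pmei(truth: CircleTruth, genome: dict[str, str] | None) -> bool:
    if genome is None:
        return False
    # junction-spanning occurrences are ignored; the motif is 8 bp so the
    # approximation is harmless at simulated scales
    return any(
        PMEI_MOTIF in genome[f.chrom][f.start : f.end] for f in truth.fragments
    )


# ---------------------------------------------------------------------------
# truth


def _draw_size(dist: dict, rng: np.random.Generator) -> int:
    kind = dist.get("kind", "lognormal")
    if kind == "loguniform":
        lo, hi = dist["min"], dist["max"]
        return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    if kind == "lognormal":
        median = dist["median"]
        if dist.get("second_mode_weight", 0) > 0 and rng.random() < dist["second_mode_weight"]:
            median = dist["second_mode_median"]
        size = rng.lognormal(np.log(median), dist.get("sigma", 0.8))
        return max(int(dist.get("min", 150)), int(round(size)))
    raise ValueError(f"unknown size distribution {kind!r}")


def assign_clones(config: SimConfig) -> dict[str, CloneSpec]:
    """Deterministic largest-remainder allocation of cells to clones,
    shuffled under the config seed."""
    cells = config.cell_ids()
    fractions = np.array([c.fraction for c in config.clone_spec])
    counts = np.floor(fractions * len(cells)).astype(int)
    remainder = fractions * len(cells) - counts
    for i in np.argsort(-remainder)[: len(cells) - counts.sum()]:
        counts[i] += 1
    order = config.rng(_S_TRUTH, 10**6).permutation(len(cells))
    assignment: dict[str, CloneSpec] = {}
    cursor = 0
    for clone, n in zip(config.clone_spec, counts):
        for idx in order[cursor : cursor + n]:
            assignment[cells[idx]] = clone
        cursor += n
    return assignment


def plant_truth(
    config: SimConfig, genome: dict[str, str] | None = None
) -> list[CircleTruth]:
    """Per-cell circle truth: Poisson(small_circle_rate) private small
    circles, the cell's clone amplicons with drawn copy numbers, and one
    mtDNA circle per cell.  Small circles within a cell are placed with
    rejection sampling to keep >= ``min_separation`` bp apart (real small
    circles essentially never stack, and separation keeps per-cell calls
    unambiguous)."""
    nuclear = [c for c in config.chrom_sizes if c != "chrM"]
    if not nuclear:
        raise ValueError("need at least one non-chrM chromosome")
    lengths = np.array([config.chrom_sizes[c] for c in nuclear], dtype=float)
    amp_by_name = {a.name: a for a in config.ecdna_spec}
    assignment = assign_clones(config)
    truths: list[CircleTruth] = []
    for ci, cell in enumerate(config.cell_ids()):
        rng = config.rng(_S_TRUTH, ci)
        clone = assignment[cell]
        for amp_name in clone.amplicons:
            amp = amp_by_name[amp_name]
            cn = amp.draw_cn(rng)
            if cn < 1:
                continue  # this cell lacks the amplicon entirely
            truth = CircleTruth(
                cell_id=cell,
                fragments=[dataclasses.replace(f) for f in amp.fragments],
                copy_number=cn,
                origin="ecdna",
                name=amp_name,
            )
            truth.contains_pmei_site = _contains_pmei(truth, genome)
            truths.append(truth)
        n_small = rng.poisson(config.small_circle_rate)
        placed: list[GenomicInterval] = []
        for si in range(n_small):
            size = _draw_size(config.small_circle_size_dist, rng)
            for _attempt in range(200):
                chrom = nuclear[rng.choice(len(nuclear), p=lengths / lengths.sum())]
                limit = config.chrom_sizes[chrom] - size
                if limit <= 0:
                    continue
                start = int(rng.integers(0, limit))
                iv = GenomicInterval(chrom, start, start + size)
                pad = config.min_separation
                if all(
                    not GenomicInterval(
                        iv.chrom, max(0, iv.start - pad), iv.end + pad
                    ).overlaps(p)
                    for p in placed
                ):
                    placed.append(iv)
                    break
            else:
                continue
            truth = CircleTruth(
                cell_id=cell, fragments=[placed[-1]], copy_number=1,
                origin="small", name=f"{cell}_small{si}",
            )
            truth.contains_pmei_site = _contains_pmei(truth, genome)
            truths.append(truth)
        if "chrM" in config.chrom_sizes:
            mt = CircleTruth(
                cell_id=cell,
                fragments=[GenomicInterval("chrM", 0, config.chrom_sizes["chrM"])],
                copy_number=config.mt_copy_number,
                origin="chrM",
                name="chrM",
            )
            mt.contains_pmei_site = True if genome is None else _contains_pmei(mt, genome)
            truths.append(mt)
    return truths


def write_truth_tsv(truths: Sequence[CircleTruth], path) -> None:
    rows = []
    for t in truths:
        frags = ";".join(f"{f.chrom}:{f.start}-{f.end}" for f in t.fragments)
        rows.append(
            dict(cell_id=t.cell_id, name=t.name, fragments=frags, length=t.length,
                 copy_number=t.copy_number, origin=t.origin,
                 contains_pmei_site=int(t.contains_pmei_site))
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reads


def _circle_to_ref(
    fragments: list[GenomicInterval], pos: int, length: int
) -> list[tuple[str, int, int]]:
    """Map a circle-coordinate segment [pos, pos+length) (mod circle) to
    reference pieces, splitting at fragment boundaries (junctions)."""
    total = sum(len(f) for f in fragments)
    pieces: list[tuple[str, int, int]] = []
    remaining = length
    cursor = pos % total
    while remaining > 0:
        offset = 0
        for frag in fragments:
            if cursor < offset + len(frag):
                within = cursor - offset
                take = min(remaining, len(frag) - within)
                pieces.append((frag.chrom, frag.start + within, frag.start + within + take))
                cursor = (cursor + take) % total
                remaining -= take
                break
            offset += len(frag)
    # merge adjacent pieces that are contiguous on the reference
    merged: list[tuple[str, int, int]] = []
    for p in pieces:
        if merged and merged[-1][0] == p[0] and merged[-1][2] == p[1]:
            merged[-1] = (p[0], merged[-1][1], p[2])
        else:
            merged.append(list(p))  # type: ignore[arg-type]
    return [tuple(p) for p in merged]


def _emit_read(
    records: list[dict],
    pieces: list[tuple[str, int, int]],
    read_id: str,
    is_read1: bool,
    is_reverse: bool,
    mate: tuple[str, int, bool],
    read_length: int,
    min_piece: int = 20,
):
    """Append SAM record dicts for one read, split across ``pieces``.

    The longest piece is primary; pieces shorter than ``min_piece`` are
    represented only as clipping.  Soft-clip lengths are complementary:
    clips on one piece cover exactly the bases aligned by the others.
    """
    kept = [i for i, p in enumerate(pieces) if p[2] - p[1] >= min_piece]
    if not kept:
        kept = [max(range(len(pieces)), key=lambda i: pieces[i][2] - pieces[i][1])]
    primary = max(kept, key=lambda i: pieces[i][2] - pieces[i][1])
    offsets = np.cumsum([0] + [p[2] - p[1] for p in pieces])
    sa_entries = {
        i: f"{pieces[i][0]},{pieces[i][1] + 1},{'-' if is_reverse else '+'},"
        f"{_cigar(offsets[i], pieces[i][2] - pieces[i][1], read_length)},60,0;"
        for i in kept
    }
    for i in kept:
        left = int(offsets[i])
        alen = pieces[i][2] - pieces[i][1]
        sa = "".join(sa_entries[j] for j in kept if j != i)
        records.append(
            dict(
                read_id=read_id,
                chrom=pieces[i][0],
                start=pieces[i][1],
                cigar=_cigar(left, alen, read_length),
                is_read1=is_read1,
                is_reverse=is_reverse,
                is_supplementary=(i != primary),
                mate=mate,
                sa=sa if len(kept) > 1 else None,
            )
        )


def _cigar(left_clip: int, aligned: int, read_length: int) -> str:
    right = read_length - left_clip - aligned
    parts = []
    if left_clip:
        parts.append(f"{left_clip}S")
    parts.append(f"{aligned}M")
    if right > 0:
        parts.append(f"{right}S")
    return "".join(parts)


def simulate_reads(
    truths: Sequence[CircleTruth],
    config: SimConfig,
    out_dir,
    cells: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Emit one coordinate-sorted SAM file per cell.

    Circle fragments are sampled uniformly in circle coordinates at a
    rate proportional to copy number x circular retention; fragments
    wrapping the circle origin produce outward-facing pairs and reads
    crossing a junction produce SA-tagged split alignments.  Linear
    background is uniform at background_depth x linear retention.  Under
    ``pmei_exo5d`` circles carrying the PmeI motif are down-weighted to
    linear retention.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    circ_ret, lin_ret = config.retention()
    pmei_mode = config.condition == "pmei_exo5d"
    R = config.read_length
    cells = list(cells) if cells is not None else config.cell_ids()
    by_cell: dict[str, list[CircleTruth]] = {c: [] for c in cells}
    for t in truths:
        if t.cell_id in by_cell:
            by_cell[t.cell_id].append(t)
    chroms = list(config.chrom_sizes)
    chrom_lengths = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    paths: dict[str, Path] = {}
    header = pysam.AlignmentHeader.from_references(
        chroms, [config.chrom_sizes[c] for c in chroms]
    )
    for ci, cell in enumerate(cells):
        rng = config.rng(_S_READS, ci)
        records: list[dict] = []
        for ti, truth in enumerate(by_cell[cell]):
            retention = lin_ret if (pmei_mode and truth.contains_pmei_site) else circ_ret
            L = truth.length
            coverage = config.circle_depth_per_copy * truth.copy_number * retention
            n_frags = int(rng.poisson(coverage * L / (2.0 * R)))
            starts = rng.integers(0, L, size=n_frags) if n_frags else np.array([], int)
            inserts = np.clip(
                rng.normal(config.mean_insert, config.insert_sd, size=n_frags),
                2 * R, None,
            ).astype(int)
            inserts = np.minimum(inserts, L)
            # guarantee a minimum number of junction-spanning fragments for
            # single-fragment circles shorter than the genome (the caller's
            # evidence model needs them; coverage makes them abundant anyway)
            n_j = int(np.sum((starts + inserts) > L))
            need = config.min_junction_fragments - n_j
            if need > 0 and L > 2 * R:
                ins = min(max(2 * R + 10, config.mean_insert), L)
                extra_starts = L - rng.integers(1, min(ins, R), size=need)
                starts = np.concatenate([starts, extra_starts])
                inserts = np.concatenate([inserts, np.full(need, ins, int)])
            for fi, (s, ins) in enumerate(zip(starts, inserts)):
                rid = f"{cell}:t{ti}:f{fi}"
                r1_pieces = _circle_to_ref(truth.fragments, int(s), R)
                r2_pieces = _circle_to_ref(truth.fragments, int(s + ins - R), R)
                if config.mismap_rate and rng.random() < config.mismap_rate:
                    ch = chroms[rng.choice(len(chroms), p=chrom_lengths / chrom_lengths.sum())]
                    pos = int(rng.integers(0, max(1, config.chrom_sizes[ch] - R)))
                    r1_pieces = [(ch, pos, pos + R)]
                m1 = (r1_pieces[0][0], r1_pieces[0][1], False)
                m2 = (r2_pieces[0][0], r2_pieces[0][1], True)
                _emit_read(records, r1_pieces, rid, True, False, m2, R)
                _emit_read(records, r2_pieces, rid, False, True, m1, R)
        # linear background
        bg_cov = config.background_depth * lin_ret
        n_bg = int(rng.poisson(bg_cov * chrom_lengths.sum() / (2.0 * R)))
        if n_bg:
            bchrom = rng.choice(len(chroms), size=n_bg, p=chrom_lengths / chrom_lengths.sum())
            for bi in range(n_bg):
                ch = chroms[bchrom[bi]]
                clen = config.chrom_sizes[ch]
                ins = int(np.clip(rng.normal(config.mean_insert, config.insert_sd), 2 * R, None))
                ins = min(ins, clen)
                pos = int(rng.integers(0, max(1, clen - ins + 1)))
                rid = f"{cell}:bg:{bi}"
                p1 = [(ch, pos, pos + R)]
                p2 = [(ch, pos + ins - R, pos + ins)]
                _emit_read(records, p1, rid, True, False, (ch, p2[0][1], True), R)
                _emit_read(records, p2, rid, False, True, (ch, pos, False), R)
        path = out_dir / f"{cell}.sam"
        _write_sam(records, header, path, cell)
        paths[cell] = path
    return paths


def _write_sam(records: list[dict], header: pysam.AlignmentHeader, path, cell: str) -> None:
    records.sort(key=lambda r: (r["chrom"], r["start"], r["read_id"], r["is_supplementary"]))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec["read_id"]
            a.reference_name = rec["chrom"]
            a.reference_start = rec["start"]
            a.mapping_quality = 60
            a.cigarstring = rec["cigar"]
            flag = 0x1 | 0x2  # paired, proper
            flag |= 0x40 if rec["is_read1"] else 0x80
            if rec["is_reverse"]:
                flag |= 0x10
            mate_chrom, mate_start, mate_rev = rec["mate"]
            if mate_rev:
                flag |= 0x20
            if rec["is_supplementary"]:
                flag |= 0x800
            a.flag = flag
            a.next_reference_name = mate_chrom
            a.next_reference_start = mate_start
            a.template_length = 0
            tags = [("CB", cell)]
            if rec["sa"]:
                tags.append(("SA", rec["sa"]))
            a.set_tags(tags)
            out.write(a)


# ---------------------------------------------------------------------------
# genes and expression


def make_genes(config: SimConfig) -> list[GenomicInterval]:
    """Gene annotation: one gene per amplicon fragment (named after the
    amplicon, so MYCN-style dosage questions are addressable) plus
    uniformly placed background genes on the nuclear chromosomes."""
    rng = config.rng(_S_GENES)
    genes: list[GenomicInterval] = []
    for amp in config.ecdna_spec:
        for i, frag in enumerate(amp.fragments):
            name = amp.name if i == 0 else f"{amp.name}_frag{i}"
            width = max(200, int(len(frag) * 0.5))
            start = frag.start + (len(frag) - width) // 2
            genes.append(GenomicInterval(frag.chrom, start, start + width, name))
    nuclear = [c for c in config.chrom_sizes if c != "chrM"]
    lengths = np.array([config.chrom_sizes[c] for c in nuclear], dtype=float)
    amp_frags = [f for a in config.ecdna_spec for f in a.fragments]
    for gi in range(config.n_genes):
        size = max(500, int(rng.lognormal(np.log(20_000), 0.7)))
        for _attempt in range(50):
            chrom = nuclear[rng.choice(len(nuclear), p=lengths / lengths.sum())]
            width = min(size, config.chrom_sizes[chrom] - 1)
            start = int(rng.integers(0, config.chrom_sizes[chrom] - width))
            gene = GenomicInterval(chrom, start, start + width, f"gene{gi:04d}")
            # background genes stay clear of amplicon fragments so the
            # amplicon/background split of the dosage model is unambiguous
            if not any(gene.overlaps(f) for f in amp_frags):
                genes.append(gene)
                break
    return genes


def simulate_expression(
    truths: Sequence[CircleTruth],
    genes: Sequence[GenomicInterval],
    config: SimConfig,
) -> pd.DataFrame:
    """Gene x cell count matrix, negative-binomial with mean
    baseline_g x CN^coupling for genes on a cell's ecDNA amplicons
    (CN = that amplicon's copy number in the cell) and baseline_g
    elsewhere.  Dispersion -> 0 degenerates to Poisson.
    """
    for g in genes:
        if len(g) == 0:
            raise ValueError(f"gene {g.name!r} has zero length")
    rng = config.rng(_S_EXPR)
    gene_names = [g.name for g in genes]
    baselines = rng.lognormal(np.log(config.baseline_mean), 0.6, size=len(genes))
    cells = config.cell_ids()
    amp_cn: dict[str, dict[str, int]] = {c: {} for c in cells}
    for t in truths:
        if t.origin == "ecdna" and t.cell_id in amp_cn:
            amp_cn[t.cell_id][t.name] = t.copy_number
    amp_genes: dict[str, list[int]] = {}
    for amp in config.ecdna_spec:
        idx = [
            i for i, g in enumerate(genes)
            if any(g.overlaps(f) for f in amp.fragments)
        ]
        amp_genes[amp.name] = idx
    counts = np.zeros((len(genes), len(cells)), dtype=int)
    d = config.expression_dispersion
    for j, cell in enumerate(cells):
        mult = np.ones(len(genes))
        for amp_name, cn in amp_cn[cell].items():
            if cn >= 1:
                mult[amp_genes[amp_name]] = float(cn) ** config.expression_coupling
        mean = baselines * mult
        if d > 0:
            lam = rng.gamma(shape=1.0 / d, scale=mean * d)
        else:
            lam = mean
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(counts, index=gene_names, columns=cells)


# ---------------------------------------------------------------------------
# mtDNA pileups


def simulate_mt_pileups(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Per-cell allele-count tables over mtDNA positions.

    Rows: position, ref, A/C/G/T counts.  At a clone's variant positions
    the alt count is Binomial(depth, heteroplasmy fraction); everywhere
    else non-ref alleles appear at the uniform error rate.  Depth-0
    positions are emitted with zero counts (AF undefined downstream).
    """
    if "chrM" not in config.chrom_sizes:
        raise ValueError("config lacks chrM")
    for clone in config.clone_spec:
        for pos, alt, frac in clone.mt_variants:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"heteroplasmy fraction {frac} outside [0, 1] "
                    f"(clone {clone.name!r}, position {pos})"
                )
    mt_len = config.chrom_sizes["chrM"]
    rng0 = config.rng(_S_MT, 10**6)
    var_positions = sorted(
        {pos for clone in config.clone_spec for pos, _, _ in clone.mt_variants}
    )
    noise_pool = np.setdiff1d(
        rng0.integers(0, mt_len, size=config.n_noise_positions * 3), var_positions
    )
    noise_positions = sorted(noise_pool[: config.n_noise_positions].tolist())
    positions = sorted(set(var_positions) | set(noise_positions))
    bases = ["A", "C", "G", "T"]
    alt_by_pos = {
        pos: alt
        for clone in config.clone_spec
        for pos, alt, _ in clone.mt_variants
    }
    ref_by_pos = {}
    for pos, i in zip(positions, rng0.integers(0, 4, size=len(positions))):
        ref = bases[i]
        if ref == alt_by_pos.get(pos):  # reference must differ from the alt
            ref = bases[(i + 1) % 4]
        ref_by_pos[pos] = ref
    assignment = assign_clones(config)
    out: dict[str, pd.DataFrame] = {}
    for ci, cell in enumerate(config.cell_ids()):
        rng = config.rng(_S_MT, ci)
        clone = assignment[cell]
        variant_at = {pos: (alt, frac) for pos, alt, frac in clone.mt_variants}
        rows = []
        for pos in positions:
            ref = ref_by_pos[pos]
            depth = int(rng.poisson(config.mt_pileup_depth))
            counts = {b: 0 for b in bases}
            if depth > 0:
                alt, frac = variant_at.get(pos, (None, 0.0))
                n_alt = int(rng.binomial(depth, frac)) if alt else 0
                if alt:
                    counts[alt] += n_alt
                n_err = int(rng.binomial(depth - n_alt, config.mt_error_rate))
                for b in rng.integers(0, 4, size=n_err):
                    counts[bases[b]] += 1
                counts[ref] += depth - n_alt - n_err
            rows.append({"pos": pos, "ref": ref, **counts})
        out[cell] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# SNP allele counts for phasing


def simulate_snp_counts(
    truths: Sequence[CircleTruth], config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heterozygous SNPs across amplicon fragments, with bulk and
    per-cell allele counts reflecting mono-allelic amplification: the alt
    allele rides the ecDNA, so BAF = (1 + CN) / (2 + CN) at copy number
    CN (two chromosomal copies, one of which gained).

    Returns (bulk table, per-cell long table).
    """
    if not config.ecdna_spec:
        raise ValueError("no amplicons configured")
    rng = config.rng(_S_SNP)
    cells = config.cell_ids()
    cn_by_cell: dict[str, dict[str, int]] = {c: {} for c in cells}
    for t in truths:
        if t.origin == "ecdna":
            cn_by_cell[t.cell_id][t.name] = t.copy_number
    snps = []
    for amp in config.ecdna_spec:
        for si in range(config.snps_per_amplicon):
            frag = amp.fragments[si % len(amp.fragments)]
            pos = int(rng.integers(frag.start, frag.end))
            snps.append((amp.name, frag.chrom, pos))
    mean_cn = {
        amp.name: float(
            np.mean([cn_by_cell[c].get(amp.name, 0) for c in cells]) or 0.0
        )
        for amp in config.ecdna_spec
    }
    bulk_rows, cell_rows = [], []
    for amp_name, chrom, pos in snps:
        baf_bulk = (1.0 + mean_cn[amp_name]) / (2.0 + mean_cn[amp_name])
        depth = int(rng.poisson(config.snp_bulk_depth))
        n_alt = int(rng.binomial(depth, baf_bulk)) if depth else 0
        bulk_rows.append(
            dict(chrom=chrom, pos=pos, amplicon=amp_name, ref="A", alt="G",
                 alt_count=n_alt, depth=depth)
        )
        for cell in cells:
            cn = cn_by_cell[cell].get(amp_name, 0)
            baf = (1.0 + cn) / (2.0 + cn)
            d = int(rng.poisson(config.snp_cell_depth))
            a = int(rng.binomial(d, baf)) if d else 0
            cell_rows.append(
                dict(cell_id=cell, chrom=chrom, pos=pos, amplicon=amp_name,
                     alt_count=a, depth=d)
            )
    return pd.DataFrame(bulk_rows), pd.DataFrame(cell_rows)


# ---------------------------------------------------------------------------
# chromatin track


def simulate_chromatin_track(
    config: SimConfig, bin_size: int = 100, n_peaks: int = 50
):
    """A smooth nonnegative signal track (CPM-like) plus a matching peak
    BED: Gaussian bumps on a low background.  Used by examples and the
    end-to-end pipeline as a stand-in chromatin mark."""
    from .io_core import SignalTrack

    rng = config.rng(_S_TRACK)
    data: dict[str, np.ndarray] = {}
    peaks: list[GenomicInterval] = []
    nuclear = {c: l for c, l in config.chrom_sizes.items() if c != "chrM"}
    total = sum(nuclear.values())
    for chrom, length in config.chrom_sizes.items():
        n_bins = -(-length // bin_size)
        values = np.full(n_bins, 0.1)
        if chrom in nuclear:
            k = max(1, int(round(n_peaks * length / total)))
            centers = rng.integers(0, n_bins, size=k)
            widths = rng.integers(3, 15, size=k)
            heights = rng.lognormal(np.log(5), 0.5, size=k)
            x = np.arange(n_bins)
            for c, w, h in zip(centers, widths, heights):
                values += h * np.exp(-0.5 * ((x - c) / w) ** 2)
                lo = max(0, (c - w) * bin_size)
                hi = min(length, (c + w) * bin_size)
                if lo < hi:
                    peaks.append(GenomicInterval(chrom, int(lo), int(hi)))
        data[chrom] = values
    from .io_core import merge_intervals

    return SignalTrack(bin_size=bin_size, data=data), merge_intervals(peaks)
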