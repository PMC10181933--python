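"""End-to-end orchestration with a config file and a run manifest.

The config is YAML.  A ``sim`` block generates inputs with the built-in
generator; otherwise the stages read the paths named in the config.
Stages run in dependency order (simulate -> call -> qc -> recurrence /
co-occurrence -> dosage -> microhomology -> chromatin test -> lineage);
a cell whose calling stage fails is quarantined (logged and dropped),
not fatal to the run.  Every output is listed in ``manifest.json`` with
its checksum, the config snapshot and the seeds, so a rerun with the
same config and seed is byte-identical and traceable.

Cells are independent work units: results do not depend on the order
they are processed in.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import circlecall, chromatin, dosage, lineage, qc, recurrence, sim
from .io_core import (
    GenomicInterval,
    parse_alignments,
    read_bed,
    write_bed,
    write_chrom_sizes,
)
from .junctions import extract_junction_windows, score_microhomology

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError("config must be a YAML mapping")
    return config


def _build_sim_config(block: dict, seed: int | None) -> sim.SimConfig:
    block = dict(block)
    amplicons = [
        sim.AmpliconSpec(
            name=a["name"],
            fragments=[GenomicInterval(*f) for f in a["fragments"]],
            cn_dist=tuple(a.get("cn_dist", ("lognormal", 20.0, 0.5))),
        )
        for a in block.pop("ecdna_spec", [])
    ]
    clones = [
        sim.CloneSpec(
            name=c.get("name", f"clone{i}"),
            fraction=float(c.get("fraction", 1.0)),
            amplicons=list(c.get("amplicons", [])),
            mt_variants=[tuple(v) for v in c.get("mt_variants", [])],
        )
        for i, c in enumerate(block.pop("clone_spec", [{"name": "clone1", "fraction": 1.0}]))
    ]
    if seed is not None:
        block["seed"] = seed
    return sim.SimConfig(ecdna_spec=amplicons, clone_spec=clones, **block)


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config_path, out_dir, seed: int | None = None) -> dict:
    """Run every applicable stage; returns the manifest dict."""
    config = load_config(config_path)
    if "sim" not in config and "inputs" not in config:
        raise ValueError("config needs a 'sim' block or an 'inputs' block")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "circlescope",
        "version": __version__,
        "config": config,
        "seed": seed,
        "outputs": {},
        "quarantined_cells": [],
    }

    params = config.get("params", {})
    fdr = float(params.get("fdr", 0.001))
    min_support = int(params.get("min_support", 2))
    edge_slack = int(params.get("edge_slack", 150))
    max_gap = int(params.get("max_gap", 500))

    def register(key: str, path: Path) -> None:
        manifest["outputs"][key] = {
            "path": str(path.relative_to(out)),
            "sha256": _checksum(path),
        }

    # ---------------- stage: inputs (simulate or load) ----------------
    if "sim" in config:
        scfg = _build_sim_config(config["sim"], seed)
        genome = sim.make_genome(scfg, out / "genome.fa")
        write_chrom_sizes(scfg.chrom_sizes, out / "genome.chrom.sizes")
        truths = sim.plant_truth(scfg, genome)
        sim.write_truth_tsv(truths, out / "truth.tsv")
        sam_paths = sim.simulate_reads(truths, scfg, out / "alignments")
        genes = sim.make_genes(scfg)
        write_bed(genes, out / "genes.bed")
        expr = sim.simulate_expression(truths, genes, scfg)
        expr.to_csv(out / "expression.tsv", sep="\t")
        pileups = sim.simulate_mt_pileups(scfg)
        (out / "mt_pileups").mkdir(exist_ok=True)
        for cell, table in pileups.items():
            table.to_csv(out / "mt_pileups" / f"{cell}.tsv", sep="\t", index=False)
        track, peaks = sim.simulate_chromatin_track(scfg)
        from .io_core import write_bedgraph

        write_bedgraph(track, out / "chromatin.bedgraph", scfg.chrom_sizes)
        write_bed(peaks, out / "peaks.bed")
        if scfg.ecdna_spec:
            bulk_snps, cell_snps = sim.simulate_snp_counts(truths, scfg)
            bulk_snps.to_csv(out / "snps_bulk.tsv", sep="\t", index=False)
            cell_snps.to_csv(out / "snps_cells.tsv", sep="\t", index=False)
        chrom_sizes = scfg.chrom_sizes
        amplicon_bed = {
            a.name: [dataclasses.replace(f, name=a.name) for f in a.fragments]
            for a in scfg.ecdna_spec
        }
        cells = scfg.cell_ids()
        for key in ("genome.fa", "genome.chrom.sizes", "truth.tsv", "genes.bed",
                    "expression.tsv", "chromatin.bedgraph", "peaks.bed"):
            register(key, out / key)
    else:
        inputs = config["inputs"]
        from .io_core import read_chrom_sizes, read_counts_tsv

        chrom_sizes = read_chrom_sizes(inputs["chrom_sizes"])
        sam_paths = {Path(p).name.split(".")[0]: Path(p) for p in inputs["alignments"]}
        cells = sorted(sam_paths)
        genes = read_bed(inputs["genes"]) if "genes" in inputs else []
        expr = read_counts_tsv(inputs["expression"]) if "expression" in inputs else None
        amplicon_bed = {}
        if "amplicons" in inputs:
            for iv in read_bed(inputs["amplicons"]):
                amplicon_bed.setdefault(iv.name or "amplicon", []).append(iv)
        pileups = {}
        if "mt_pileups" in inputs:
            pileups = {
                Path(p).name.split(".")[0]: pd.read_csv(p, sep="\t")
                for p in inputs["mt_pileups"]
            }
        genome = None

    # ---------------- stage: per-cell circle calling ----------------
    reads_by_cell: dict[str, list] = {}
    circles_by_cell: dict[str, list] = {}
    calls_dir = out / "circles"
    calls_dir.mkdir(exist_ok=True)
    for cell in cells:
        try:
            reads = list(parse_alignments(sam_paths[cell], cell_id=cell))
            calls = circlecall.call_circles(
                reads, chrom_sizes, fdr=fdr, max_gap=max_gap,
                edge_slack=edge_slack, min_support=min_support,
            )
        except Exception as exc:  # quarantine, not fatal
            manifest["quarantined_cells"].append({"cell": cell, "error": str(exc)})
            continue
        reads_by_cell[cell] = reads
        circles_by_cell[cell] = calls
        classified = [c.interval for c in calls if c.classified]
        for c in calls:
            if c.classified:
                c.interval.name = f"{cell}_circle"
        write_bed(classified, calls_dir / f"{cell}.circles.bed")
    rows = []
    for cell in sorted(circles_by_cell):
        for c in circles_by_cell[cell]:
            if c.classified:
                rows.append(dict(
                    cell_id=cell, chrom=c.interval.chrom, start=c.interval.start,
                    end=c.interval.end, n_split=c.n_split, n_outward=c.n_outward,
                    total_reads=c.total_reads, q=c.enrichment_q,
                ))
    pd.DataFrame(rows).to_csv(out / "circles.tsv", sep="\t", index=False)
    register("circles.tsv", out / "circles.tsv")

    # ---------------- stage: QC ----------------
    dna = [
        qc.dna_qc(reads_by_cell[c], chrom_sizes.get("chrM", 1),
                  sample_type=config.get("sample_type", "cell_line"), cell_id=c)
        for c in sorted(reads_by_cell)
    ]
    rna = None
    if expr is not None:
        rna = qc.rna_qc(
            expr, config.get("sample_type", "cell_line"),
            min_features={"cell_line": int(params.get("min_features", 5000)),
                          "t_cell": 2000, "nucleus": 2000},
        )
    qc_report = qc.qc_table(dna, rna)
    qc_report.to_csv(out / "qc.tsv", sep="\t")
    register("qc.tsv", out / "qc.tsv")

    # ---------------- stage: recurrence / co-occurrence ----------------
    bins = recurrence.make_bins(chrom_sizes, int(params.get("bin_size", 100_000)))
    raw, cpm = recurrence.bin_circle_reads(reads_by_cell, circles_by_cell, bins)
    positive = recurrence.mark_positive(raw, bins)
    amp_intervals = [iv for ivs in amplicon_bed.values() for iv in ivs]
    categories = recurrence.classify_bins(bins, amp_intervals)
    fractions, per_bin = recurrence.recurrence_fractions(positive, categories)
    cpm.to_csv(out / "bin_counts.tsv", sep="\t")
    positive.astype(int).to_csv(out / "bin_positive.tsv", sep="\t")
    fractions.rename("fraction").to_frame().to_csv(out / "recurrence.tsv", sep="\t")
    for key in ("bin_counts.tsv", "bin_positive.tsv", "recurrence.tsv"):
        register(key, out / key)
    if amplicon_bed:
        presence, combos = recurrence.ecdna_cooccurrence(circles_by_cell, amplicon_bed)
        presence.astype(int).to_csv(out / "cooccurrence.tsv", sep="\t")
        combos.rename("n_cells").to_frame().to_csv(out / "cooccurrence_counts.tsv", sep="\t")
        register("cooccurrence.tsv", out / "cooccurrence.tsv")

    # ---------------- stage: dosage ----------------
    if amplicon_bed and genes:
        cn_rows = []
        for cell in sorted(reads_by_cell):
            cov = dosage.gene_coverage(reads_by_cell[cell], genes)
            try:
                ests = dosage.estimate_relative_cn(
                    cov, genes, circles_by_cell.get(cell), amplicon_bed, cell_id=cell
                )
            except ValueError:
                continue
            cn_rows.extend(dataclasses.asdict(e) for e in ests)
        cn_table = pd.DataFrame(cn_rows)
        cn_table.to_csv(out / "copy_number.tsv", sep="\t", index=False)
        register("copy_number.tsv", out / "copy_number.tsv")
        if expr is not None and not cn_table.empty:
            reports = []
            for amp_name in sorted(amplicon_bed):
                sub = cn_table[cn_table["amplicon_id"] == amp_name]
                cn_series = sub.set_index("cell_id")["log2_ratio"]
                gene_names = [g.name for g in genes
                              if any(g.overlaps(iv) for iv in amplicon_bed[amp_name])]
                cpm_expr = expr / expr.sum(axis=0) * 1e6
                expr_series = cpm_expr.loc[cpm_expr.index.intersection(gene_names)].sum(axis=0)
                try:
                    rep = dosage.correlate_cn_expression(cn_series, expr_series)
                except ValueError:
                    continue
                reports.append({"amplicon": amp_name, **rep})
            pd.DataFrame(reports).to_csv(out / "dosage_correlation.tsv", sep="\t", index=False)
            register("dosage_correlation.tsv", out / "dosage_correlation.tsv")
        groups = dosage.small_circle_content_groups(circles_by_cell)
        groups.to_csv(out / "content_groups.tsv", sep="\t", index=False)
        register("content_groups.tsv", out / "content_groups.tsv")

    # ---------------- stage: SNP phasing ----------------
    snps_bulk_path = out / "snps_bulk.tsv"
    if snps_bulk_path.exists():
        bulk = pd.read_csv(snps_bulk_path, sep="\t")
        cells_tab = pd.read_csv(out / "snps_cells.tsv", sep="\t")
        phased, baf = dosage.phase_snps(bulk, cells_tab)
        pd.DataFrame([dataclasses.asdict(p) for p in phased]).to_csv(
            out / "phased_snps.tsv", sep="\t", index=False
        )
        register("phased_snps.tsv", out / "phased_snps.tsv")

    # ---------------- stage: microhomology ----------------
    if genome is not None:
        mh_rows = []
        for cell in sorted(circles_by_cell):
            classified = [c.interval for c in circles_by_cell[cell] if c.classified]
            windows, skipped = extract_junction_windows(classified, genome)
            for w in windows:
                hit = score_microhomology(w)
                mh_rows.append(dict(cell_id=cell, circle_id=hit.circle_id,
                                    length=hit.length, score=hit.score,
                                    expect=hit.expect, orientation=hit.orientation,
                                    significant=hit.significant))
        pd.DataFrame(mh_rows).to_csv(out / "microhomology.tsv", sep="\t", index=False)
        register("microhomology.tsv", out / "microhomology.tsv")

    # ---------------- stage: chromatin enrichment ----------------
    track_path = out / "chromatin.bedgraph"
    if "sim" in config and track_path.exists():
        from .io_core import read_bedgraph

        track = read_bedgraph(track_path, chrom_sizes, bin_size=100)
        peaks = read_bed(out / "peaks.bed")
        pooled = sorted(
            (c.interval for calls in circles_by_cell.values() for c in calls
             if c.classified and c.interval.chrom != "chrM"),
            key=lambda iv: (iv.chrom, iv.start),
        )
        if pooled:
            n_perm = int(params.get("n_permutations", 200))
            results = []
            for mark, stat in (
                ("signal", chromatin.make_weighted_signal_stat(track)),
                ("peak_edges", chromatin.make_edge_overlap_stat(peaks)),
            ):
                res = chromatin.randomization_test(
                    stat, pooled, chrom_sizes, n_permutations=n_perm,
                    seed=(seed or 0) + 17, mark=mark,
                )
                results.append(dict(mark=mark, observed=res.observed_stat,
                                    p_enriched=res.p_enriched,
                                    p_depleted=res.p_depleted,
                                    direction=res.direction))
            pd.DataFrame(results).to_csv(out / "chromatin_enrichment.tsv",
                                         sep="\t", index=False)
            register("chromatin_enrichment.tsv", out / "chromatin_enrichment.tsv")

    # ---------------- stage: lineage ----------------
    if pileups:
        calls_a = [c for cell, t in sorted(pileups.items())
                   for c in lineage.pileup_call(t, cell, min_af=0.01, min_alt=3,
                                                caller_tag="strict")]
        calls_b = [c for cell, t in sorted(pileups.items())
                   for c in lineage.pileup_call(t, cell, min_af=0.005, min_alt=2,
                                                caller_tag="lenient")]
        retained = lineage.consensus_filter(calls_a, calls_b)
        if retained:
            af = lineage.build_af_matrix(pileups, retained)
            try:
                filtered, log = lineage.filter_af_matrix(af)
            except ValueError:
                filtered, log = af, ["filtering removed everything; kept raw matrix"]
            filtered.to_csv(out / "af_matrix.tsv", sep="\t")
            (out / "af_filter.log").write_text("\n".join(log) + "\n")
            if filtered.shape[0] >= 2:
                k = int(params.get("n_clones", 2))
                link, labels, ids, _mask = lineage.cluster_cells(
                    filtered, n_clusters=min(k, filtered.shape[0])
                )
                labels.rename("clone").to_frame().to_csv(out / "clones.tsv", sep="\t")
                (out / "dendrogram.nwk").write_text(lineage.to_newick(link, ids) + "\n")
                register("clones.tsv", out / "clones.tsv")
                register("dendrogram.nwk", out / "dendrogram.nwk")
            register("af_matrix.tsv", out / "af_matrix.tsv")

    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
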