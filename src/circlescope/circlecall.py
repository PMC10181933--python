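"""Per-cell circle classification from enriched regions + junction evidence.

The classifier is two-step.  Step one separates the circle-supporting
evidence (split reads and outward-facing pairs) from the full alignment
stream.  Step two detects regions of read enrichment over the genomic
background at FDR < 0.001 using variable-width windows, then intersects
the *edges* of those regions with the evidence reads; a region backed by
at least two circle-supporting reads at its edges is called circular.

Enrichment detection is merge-then-Poisson: read starts are binned,
bins exceeding a background-calibrated threshold are merged into
variable-width candidate regions (within ``max_gap``), each candidate is
scored with a one-sided Poisson upper tail against the genome-wide start
rate (expected counts padded by the merge gap to blunt selection bias),
and Benjamini-Hochberg controls the FDR across candidates.  Ties in the
BH ranking are broken by genomic position for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import GenomicInterval, ReadRecord

__all__ = [
    "CircleCall",
    "extract_circle_support",
    "detect_enriched_regions",
    "classify_circles",
    "call_circles",
    "condition_metrics",
]


@dataclass
class CircleCall:
    """A classified circular region with its supporting evidence."""

    interval: GenomicInterval
    n_split: int = 0
    n_outward: int = 0
    total_reads: int = 0
    enrichment_q: float = 1.0
    classified: bool = False

    @property
    def n_support(self) -> int:
        return self.n_split + self.n_outward


def extract_circle_support(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Subset of records that constitute circle evidence: split reads
    (either piece) or members of outward-facing pairs."""
    return [r for r in reads if r.is_split or r.orientation == "outward"]


def _effective_length(
    chrom_sizes: dict[str, int], mask: list[GenomicInterval] | None
) -> float:
    total = float(sum(chrom_sizes.values()))
    if mask:
        from .io_core import merge_intervals

        total -= sum(len(m) for m in merge_intervals(mask))
    return total


def detect_enriched_regions(
    reads: list[ReadRecord],
    chrom_sizes: dict[str, int],
    fdr: float = 0.001,
    max_gap: int = 500,
    bin_size: int = 50,
    bin_p: float = 1e-4,
    mask: list[GenomicInterval] | None = None,
) -> list[tuple[GenomicInterval, float]]:
    """Variable-width enriched regions with BH-adjusted q < ``fdr``.

    Returns ``(interval, q)`` sorted by position.  Empty input yields an
    empty list with a warning.
    """
    if not reads:
        warnings.warn("no reads supplied; no enriched regions")
        return []
    eff_len = _effective_length(chrom_sizes, mask)

    by_chrom: dict[str, list[ReadRecord]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    counts_by_chrom: dict[str, np.ndarray] = {}
    for chrom, recs in by_chrom.items():
        n_bins = -(-chrom_sizes[chrom] // bin_size)
        counts_by_chrom[chrom] = np.bincount(
            np.array([r.start for r in recs]) // bin_size, minlength=n_bins
        )
    all_counts = np.concatenate(list(counts_by_chrom.values()))
    n_total_bins = max(1, int(eff_len // bin_size))

    # background start rate: begin with the genome-wide rate, then
    # iteratively exclude bins above the enrichment threshold so that
    # heavily circle-loaded cells do not inflate their own background
    rate = len(reads) / eff_len
    for _ in range(8):
        t = max(2, int(stats.poisson.ppf(1.0 - bin_p, rate * bin_size)) + 1)
        keep = all_counts < t
        n_keep = int(keep.sum()) + (n_total_bins - all_counts.size)
        new_rate = float(all_counts[keep].sum()) / max(1, n_keep * bin_size)
        if abs(new_rate - rate) <= 1e-12:
            break
        rate = new_rate
    # cells with a very high circular load can still inflate the mean;
    # the median bin count (zero-padded to the effective genome) is
    # robust to them and caps the estimate whenever it is informative
    padded_median = float(
        np.median(np.pad(all_counts, (0, max(0, n_total_bins - all_counts.size))))
    )
    if padded_median > 0:
        rate = min(rate, padded_median / bin_size)
    lam_bin = rate * bin_size
    t = max(2, int(stats.poisson.ppf(1.0 - bin_p, lam_bin)) + 1)

    candidates: list[tuple[GenomicInterval, int]] = []  # (region, count)
    gap_bins = max(1, max_gap // bin_size)
    for chrom, recs in sorted(by_chrom.items()):
        n_bins = -(-chrom_sizes[chrom] // bin_size)
        starts = np.array([r.start for r in recs])
        ends = np.array([r.end for r in recs])
        counts = counts_by_chrom[chrom]
        marked = np.flatnonzero(counts >= t)
        if marked.size == 0:
            # degenerate/sparse input: fall back to merging raw reads so a
            # lone cluster still surfaces as a (non-significant) candidate
            order = np.argsort(starts, kind="stable")
            run_start = run_end = None
            for i in order:
                if run_end is not None and starts[i] <= run_end + max_gap:
                    run_end = max(run_end, ends[i])
                else:
                    if run_start is not None:
                        candidates.append(_mk_candidate(chrom, run_start, run_end, starts, ends))
                    run_start, run_end = starts[i], ends[i]
            if run_start is not None:
                candidates.append(_mk_candidate(chrom, run_start, run_end, starts, ends))
            continue
        # two-level run construction: maximal runs of bins holding a weak
        # occupancy threshold t2 form the candidate skeleton, but only runs
        # seeded by at least one strong (>= t) bin survive; seeded runs then
        # merge across gaps up to max_gap.  Interior coverage dips of a true
        # circle stay bridged while background read clumps near an edge,
        # which lack a strong seed, can never attach to a region.
        t2 = max(2, int(np.ceil(lam_bin)) + 1)
        occupied = counts >= t2
        edges = np.flatnonzero(np.diff(np.concatenate([[0], occupied.view(np.int8), [0]])))
        weak_runs = [
            (int(lo), int(hi - 1), bool(counts[lo:hi].max() >= t))
            for lo, hi in zip(edges[::2], edges[1::2])
        ]
        groups: list[list[tuple[int, int, bool]]] = []
        for run in weak_runs:
            if groups and run[0] - groups[-1][-1][1] - 1 <= gap_bins:
                groups[-1].append(run)
            else:
                groups.append([run])
        merged_runs: list[tuple[int, int]] = []
        for group in groups:
            # trim weak runs without a strong seed at the group edges: a
            # background clump near a true circle must not shift the
            # boundary, while unseeded dips inside the group stay bridged
            while group and not group[0][2]:
                group.pop(0)
            while group and not group[-1][2]:
                group.pop()
            if group:
                merged_runs.append((group[0][0], group[-1][1]))
        for blo, bhi in merged_runs:
            in_run = (starts >= blo * bin_size) & (starts < (bhi + 1) * bin_size)
            region_start = int(starts[in_run].min())
            # clamp near the last supported bin so stray background reads
            # that start inside the run cannot drag the edge far outward
            region_end = int(min(ends[in_run].max(), (bhi + 2) * bin_size))
            candidates.append(
                (GenomicInterval(chrom, region_start, region_end), int(in_run.sum()))
            )

    if not candidates:
        return []
    # a single read can never constitute enrichment, whatever the rate
    pvals = np.array(
        [
            stats.poisson.sf(count - 1, rate * (len(region) + 2 * max_gap))
            if count >= 2
            else 1.0
            for region, count in candidates
        ]
    )
    order = sorted(
        range(len(candidates)),
        key=lambda i: (pvals[i], candidates[i][0].chrom, candidates[i][0].start),
    )
    m = len(candidates)
    qvals = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, pvals[i] * m / (rank + 1))
        qvals[i] = running
    out = [
        (region, float(q))
        for (region, _c), q in zip(candidates, qvals)
        if q < fdr
    ]
    out.sort(key=lambda x: (x[0].chrom, x[0].start))
    return out


def _mk_candidate(chrom, run_start, run_end, starts, ends):
    sel = (starts >= run_start) & (starts < run_end)
    return (GenomicInterval(chrom, int(run_start), int(run_end)), max(1, int(sel.sum())))


def classify_circles(
    regions: list[tuple[GenomicInterval, float]],
    support_reads: list[ReadRecord],
    all_reads: list[ReadRecord] | None = None,
    edge_slack: int = 150,
    min_support: int = 2,
) -> list[CircleCall]:
    """Intersect enriched-region edges with circle-supporting reads.

    A support read counts toward a region when its alignment overlaps
    either edge window ``[start - E, start + E)`` / ``[end - E, end + E)``
    with ``E = edge_slack``.  Distinct read ids are counted once; split
    evidence takes precedence over outward-pair evidence for reads that
    are both.  Regions with n_support >= ``min_support`` are classified.
    """
    calls: list[CircleCall] = []
    by_chrom: dict[str, list[ReadRecord]] = {}
    for r in support_reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    totals_by_chrom: dict[str, np.ndarray] = {}
    if all_reads is not None:
        tmp: dict[str, list[tuple[int, int]]] = {}
        for r in all_reads:
            tmp.setdefault(r.chrom, []).append((r.start, r.end))
        totals_by_chrom = {
            c: np.array(v, dtype=int).reshape(-1, 2) for c, v in tmp.items()
        }
    for region, q in regions:
        split_ids: set[str] = set()
        outward_ids: set[str] = set()
        windows = (
            (region.start - edge_slack, region.start + edge_slack),
            (region.end - edge_slack, region.end + edge_slack),
        )
        for r in by_chrom.get(region.chrom, ()):
            if any(r.start < hi and lo < r.end for lo, hi in windows):
                if r.is_split:
                    split_ids.add(r.read_id)
                elif r.orientation == "outward":
                    outward_ids.add(r.read_id)
        outward_ids -= split_ids
        total = 0
        if region.chrom in totals_by_chrom:
            arr = totals_by_chrom[region.chrom]
            total = int(np.sum((arr[:, 0] < region.end) & (arr[:, 1] > region.start)))
        call = CircleCall(
            interval=region,
            n_split=len(split_ids),
            n_outward=len(outward_ids),
            total_reads=total,
            enrichment_q=q,
        )
        call.classified = call.n_support >= min_support
        if call.classified:
            call.interval.name = call.interval.name or "circle"
            call.interval.score = call.n_support
        calls.append(call)
    return calls


def call_circles(
    reads: list[ReadRecord],
    chrom_sizes: dict[str, int],
    fdr: float = 0.001,
    max_gap: int = 500,
    edge_slack: int = 150,
    min_support: int = 2,
    mask: list[GenomicInterval] | None = None,
) -> list[CircleCall]:
    """The full two-step classifier for one cell's alignment stream."""
    support = extract_circle_support(reads)
    regions = detect_enriched_regions(
        reads, chrom_sizes, fdr=fdr, max_gap=max_gap, mask=mask
    )
    return classify_circles(
        regions, support, all_reads=reads, edge_slack=edge_slack, min_support=min_support
    )


def condition_metrics(
    reads: list[ReadRecord],
    circles: list[CircleCall],
    pmei_targets: list[GenomicInterval] | None = None,
) -> dict[str, float]:
    """Per-cell read-fraction metrics across digestion conditions:
    fraction of reads on chrM, in classified circles, and in classified
    circles carrying a PmeI recognition site.  Fractions are computed
    over primary alignments; zero total reads flags all as NaN.
    """
    primaries = [r for r in reads if not r.is_supplementary]
    total = len(primaries)
    if total == 0:
        warnings.warn("zero total reads; fractions undefined")
        return {"frac_chrm": float("nan"), "frac_circles": float("nan"),
                "frac_pmei_circles": float("nan"), "total_reads": 0}
    classified = [c.interval for c in circles if c.classified]
    pmei = pmei_targets if pmei_targets is not None else []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in classified:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    pmei_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in pmei:
        pmei_by_chrom.setdefault(iv.chrom, []).append(iv)
    n_chrm = n_circ = n_pmei = 0
    for r in primaries:
        if r.chrom == "chrM":
            n_chrm += 1
        if any(r.start < iv.end and iv.start < r.end for iv in by_chrom.get(r.chrom, ())):
            n_circ += 1
        if any(r.start < iv.end and iv.start < r.end for iv in pmei_by_chrom.get(r.chrom, ())):
            n_pmei += 1
    return {
        "frac_chrm": n_chrm / total,
        "frac_circles": n_circ / total,
        "frac_pmei_circles": n_pmei / total,
        "total_reads": total,
    }
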