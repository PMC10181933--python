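"""Genome-binned circle positivity, recurrence fractions and ecDNA
co-occurrence across cells.

Reads from classified circles are counted per cell into 100-kb bins
tiling the canonical chromosomes and normalized to sequencing depth
(counts per million).  A bin is positive in a cell when its raw count is
enriched at P < 0.05 in a one-sided Poisson upper-tail test against that
cell's background mean over nonzero non-chrM bins (no multiple-testing
correction; the contract is the raw per-bin threshold).  Bins are
categorized ecDNA / chrM / other by overlap with the bulk-derived
amplicon reconstruction, with precedence ecDNA > chrM > other, and
recurrence is the fraction of cells with >= 1 positive bin per category.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .circlecall import CircleCall
from .io_core import GenomicInterval, ReadRecord, subtract_intervals

__all__ = [
    "make_bins",
    "bin_circle_reads",
    "mark_positive",
    "classify_bins",
    "recurrence_fractions",
    "ecdna_cooccurrence",
]


def make_bins(
    chrom_sizes: dict[str, int], bin_size: int = 100_000
) -> list[GenomicInterval]:
    """Bins tiling every chromosome; the final bin may be partial."""
    bins = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, length, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, length)))
    return bins


def _bin_index(bins: list[GenomicInterval]) -> dict[str, tuple[int, int, int]]:
    """chrom -> (first bin index, bin_size, n_bins); assumes make_bins layout."""
    index: dict[str, tuple[int, int, int]] = {}
    for i, b in enumerate(bins):
        if b.chrom not in index:
            size = len(b)
            index[b.chrom] = (i, size, 0)
        first, size, n = index[b.chrom]
        index[b.chrom] = (first, size, n + 1)
    return index


def bin_circle_reads(
    reads_by_cell: dict[str, list[ReadRecord]],
    circles_by_cell: dict[str, list[CircleCall]],
    bins: list[GenomicInterval],
    library_sizes: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell binned counts of reads from classified circles.

    A read contributes when it overlaps one of its cell's classified
    circle regions; it is assigned to the bin of its alignment start
    (deterministic for straddlers).  Returns ``(raw counts, CPM)`` as
    cells x bins frames; CPM divides by the cell's library size (total
    primary alignments unless supplied) x 1e6.
    """
    index = _bin_index(bins)
    names = [f"{b.chrom}:{b.start}-{b.end}" for b in bins]
    cells = sorted(reads_by_cell)
    raw = np.zeros((len(cells), len(bins)))
    libsize = np.zeros(len(cells))
    for ci, cell in enumerate(cells):
        reads = reads_by_cell[cell]
        primaries = [r for r in reads if not r.is_supplementary]
        libsize[ci] = (
            library_sizes[cell] if library_sizes is not None else len(primaries)
        )
        circ: dict[str, list[GenomicInterval]] = {}
        for c in circles_by_cell.get(cell, []):
            if c.classified:
                circ.setdefault(c.interval.chrom, []).append(c.interval)
        for r in primaries:
            if r.chrom not in index:
                continue
            if not any(
                r.start < iv.end and iv.start < r.end for iv in circ.get(r.chrom, ())
            ):
                continue
            first, size, n = index[r.chrom]
            b = r.start // size
            if b < n:
                raw[ci, first + b] += 1
    raw_df = pd.DataFrame(raw, index=cells, columns=names)
    with np.errstate(invalid="ignore", divide="ignore"):
        cpm = raw / np.where(libsize[:, None] > 0, libsize[:, None], np.nan) * 1e6
    return raw_df, pd.DataFrame(np.nan_to_num(cpm), index=cells, columns=names)


def mark_positive(
    raw_counts: pd.DataFrame,
    bins: list[GenomicInterval] | None = None,
    p_threshold: float = 0.05,
    min_background_bins: int = 10,
) -> pd.DataFrame:
    """Boolean cells x bins positivity matrix.

    Per cell, each bin count is tested one-sided against Poisson with
    mean equal to the cell's mean over nonzero non-chrM bins; positive
    iff p < ``p_threshold``.  Cells with fewer than
    ``min_background_bins`` nonzero bins have an unstable background and
    are flagged with a warning (their bins are still tested).
    """
    if bins is not None:
        non_chrm = np.array([b.chrom != "chrM" for b in bins])
    else:
        non_chrm = np.array([not c.startswith("chrM:") for c in raw_counts.columns])
    out = np.zeros(raw_counts.shape, dtype=bool)
    values = raw_counts.to_numpy()
    for ci in range(values.shape[0]):
        row = values[ci]
        background = row[non_chrm & (row > 0)]
        if background.size == 0:
            continue
        if background.size < min_background_bins:
            warnings.warn(
                f"cell {raw_counts.index[ci]!r}: only {background.size} nonzero "
                "bins; background estimate unstable"
            )
        total, m = background.sum(), background.size
        # leave-one-out background: a heavily amplified bin must not set
        # its own expectation (with a single nonzero bin, fall back to
        # the mean over all non-chrM bins)
        lam = np.full(row.shape, total / m)
        loo = non_chrm & (row > 0)
        if m > 1:
            lam[loo] = (total - row[loo]) / (m - 1)
        else:
            lam[loo] = total / max(1, int(non_chrm.sum()))
        pvals = stats.poisson.sf(row - 1, lam)
        out[ci] = (pvals < p_threshold) & (row > 0)
    return pd.DataFrame(out, index=raw_counts.index, columns=raw_counts.columns)


def classify_bins(
    bins: list[GenomicInterval], amplicons: list[GenomicInterval]
) -> list[str]:
    """Category per bin: ecDNA (overlaps the bulk amplicon reconstruction)
    > chrM > other."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in amplicons:
        by_chrom.setdefault(a.chrom, []).append(a)
    out = []
    for b in bins:
        if any(b.overlaps(a) for a in by_chrom.get(b.chrom, ())):
            out.append("ecDNA")
        elif b.chrom == "chrM":
            out.append("chrM")
        else:
            out.append("other")
    return out


def recurrence_fractions(
    positive: pd.DataFrame, categories: list[str]
) -> tuple[pd.Series, pd.Series]:
    """Per-category fraction of cells with >= 1 positive bin, plus the
    per-bin cell-fraction vector (for recurrence heatmaps)."""
    if positive.shape[0] == 0:
        raise ValueError("need at least one cell")
    cats = np.asarray(categories)
    values = positive.to_numpy()
    frac_by_cat = {}
    for cat in ("ecDNA", "chrM", "other"):
        mask = cats == cat
        frac_by_cat[cat] = (
            float(values[:, mask].any(axis=1).mean()) if mask.any() else 0.0
        )
    per_bin = pd.Series(values.mean(axis=0), index=positive.columns)
    return pd.Series(frac_by_cat), per_bin


def ecdna_cooccurrence(
    circles_by_cell: dict[str, list[CircleCall]],
    amplicons: dict[str, list[GenomicInterval]],
    exclusions: list[GenomicInterval] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Presence/absence of each named amplicon per cell and combination
    counts.

    Presence = any classified circle overlapping the amplicon after
    subtracting the shared/excluded intervals (regions shared between
    amplicons must not count for either).  An amplicon fully covered by
    exclusions is undetectable and rejected.
    """
    effective: dict[str, list[GenomicInterval]] = {}
    for name, ivs in amplicons.items():
        remaining = subtract_intervals(ivs, exclusions or [])
        if not remaining:
            raise ValueError(f"amplicon {name!r} fully covered by exclusions")
        effective[name] = remaining
    cells = sorted(circles_by_cell)
    names = sorted(amplicons)
    presence = pd.DataFrame(False, index=cells, columns=names)
    for cell in cells:
        classified = [c.interval for c in circles_by_cell[cell] if c.classified]
        for name in names:
            presence.loc[cell, name] = any(
                iv.overlaps(a) for iv in classified for a in effective[name]
            )
    combos = presence.apply(
        lambda row: "+".join([n for n in names if row[n]]) or "(none)", axis=1
    )
    return presence, combos.value_counts().sort_index()
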