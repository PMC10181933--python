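"""Relative ecDNA copy number, SNP phasing, dosage-expression coupling
and small-circle content grouping.

Copy number is estimated per cell as log2(mean coverage of amplicon
genes / trimmed mean coverage of non-amplicon genes): genes are split by
overlap with the cell's identified ecDNA regions (union of the cell's
classified circles and, when supplied, the bulk amplicon reconstruction,
which covers cells where the caller missed the amplicon), and the
background is robustified by removing the top and bottom 5% of
non-amplicon coverages before averaging.  A winsorizing variant (clamp
instead of remove) is available.

SNP phasing assigns each heterozygous SNP in an amplified region to the
gained or non-gained allele by a two-sided binomial test of the bulk
B-allele frequency against 0.5, then genotypes every cell at the known
positions while keeping the bulk assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circlecall import CircleCall
from .io_core import GenomicInterval, ReadRecord

__all__ = [
    "trimmed_mean",
    "gene_coverage",
    "estimate_relative_cn",
    "correlate_cn_expression",
    "phase_snps",
    "small_circle_content_groups",
    "CopyNumberEstimate",
    "PhasedSNP",
]


@dataclass
class CopyNumberEstimate:
    cell_id: str
    amplicon_id: str
    log2_ratio: float
    n_amplicon_genes: int
    background_mean: float
    from_bulk_amplicon: bool = False  # True when the cell's own calls missed it


@dataclass
class PhasedSNP:
    chrom: str
    position: int
    bulk_baf: float
    p_value: float
    allele_assignment: str  # gained | not_gained | unassigned


def trimmed_mean(values, frac: float = 0.05, winsorize: bool = False) -> float:
    """Mean after removing (or clamping, if ``winsorize``) the top and
    bottom ``frac`` of values; ``k = floor(n * frac)`` from each side."""
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        return float("nan")
    k = int(n * frac)
    if winsorize:
        arr = np.clip(arr, arr[k], arr[n - k - 1])
        return float(arr.mean())
    return float(arr[k : n - k].mean())


def gene_coverage(
    reads: list[ReadRecord], genes: list[GenomicInterval]
) -> pd.Series:
    """Mean depth per gene: aligned bases overlapping the gene / length."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    arrays = {
        c: np.array(v, dtype=float).reshape(-1, 2) for c, v in by_chrom.items()
    }
    cov = {}
    for g in genes:
        arr = arrays.get(g.chrom)
        if arr is None:
            cov[g.name] = 0.0
            continue
        overlap = np.clip(
            np.minimum(arr[:, 1], g.end) - np.maximum(arr[:, 0], g.start), 0, None
        )
        cov[g.name] = float(overlap.sum() / len(g))
    return pd.Series(cov)


def estimate_relative_cn(
    coverage: pd.Series,
    genes: list[GenomicInterval],
    circles: list[CircleCall] | None,
    amplicons: dict[str, list[GenomicInterval]],
    cell_id: str = "",
    trim_frac: float = 0.05,
    winsorize: bool = False,
    min_background_genes: int = 20,
) -> list[CopyNumberEstimate]:
    """Per-amplicon log2 coverage ratio for one cell.

    ``coverage`` indexes gene name -> mean coverage.  Amplicon genes are
    those overlapping the union of the cell's classified circles and the
    supplied amplicon intervals; the remaining genes form the trimmed
    background.
    """
    gene_by_name = {g.name: g for g in genes}
    own: list[GenomicInterval] = [
        c.interval for c in (circles or []) if c.classified
    ]
    amp_gene_names: dict[str, list[str]] = {}
    used_bulk: dict[str, bool] = {}
    all_amp_genes: set[str] = set()
    for amp_name, ivs in amplicons.items():
        from_cell = [
            g.name for g in genes if any(g.overlaps(iv) for iv in own)
            and any(g.overlaps(iv) for iv in ivs)
        ]
        names = [g.name for g in genes if any(g.overlaps(iv) for iv in ivs)]
        amp_gene_names[amp_name] = names
        used_bulk[amp_name] = len(from_cell) == 0
        all_amp_genes.update(names)
    # genes on any cell circle are excluded from background even when not
    # part of a named amplicon (they are amplified in this cell)
    for g in genes:
        if any(g.overlaps(iv) for iv in own):
            all_amp_genes.add(g.name)
    background_names = [g.name for g in genes if g.name not in all_amp_genes]
    if len(background_names) < min_background_genes:
        raise ValueError(
            f"only {len(background_names)} non-amplicon genes; "
            f"need >= {min_background_genes} for {trim_frac:.0%} trimming"
        )
    background = trimmed_mean(
        coverage.reindex(background_names).to_numpy(), trim_frac, winsorize
    )
    out = []
    for amp_name, names in amp_gene_names.items():
        if not names:
            continue
        amp_mean = float(coverage.reindex(names).mean())
        if background <= 0:
            warnings.warn(f"zero background coverage for cell {cell_id!r}")
            ratio = float("nan")
        else:
            with np.errstate(divide="ignore"):
                ratio = float(np.log2(amp_mean / background)) if amp_mean > 0 else -np.inf
        out.append(
            CopyNumberEstimate(
                cell_id=cell_id,
                amplicon_id=amp_name,
                log2_ratio=ratio,
                n_amplicon_genes=len(names),
                background_mean=background,
                from_bulk_amplicon=used_bulk[amp_name],
            )
        )
    return out


def correlate_cn_expression(
    cn: pd.Series, expression: pd.Series
) -> dict[str, float]:
    """Pearson r, two-sided p, and least-squares slope/intercept between
    the per-cell copy-number estimate and (CPM-normalized) expression of
    the amplicon genes.  Needs >= 3 cells present in both."""
    joined = pd.concat([cn.rename("cn"), expression.rename("expr")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 cells with both modalities")
    if joined["cn"].std() == 0 or joined["expr"].std() == 0:
        warnings.warn("zero variance; correlation undefined")
        return {"r": float("nan"), "p": float("nan"),
                "slope": float("nan"), "intercept": float("nan"), "n": len(joined)}
    lm = stats.linregress(joined["cn"], joined["expr"])
    return {
        "r": float(lm.rvalue),
        "p": float(lm.pvalue),
        "slope": float(lm.slope),
        "intercept": float(lm.intercept),
        "n": len(joined),
    }


def phase_snps(
    bulk: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    min_bulk_depth: int = 10,
) -> tuple[list[PhasedSNP], pd.DataFrame | None]:
    """Assign SNPs to the gained / non-gained allele from bulk BAF.

    ``bulk`` needs columns chrom, pos, alt_count, depth.  A SNP whose
    two-sided binomial test against BAF 0.5 rejects at ``p_threshold``
    is assigned (alt gained when BAF > 0.5, ref gained when < 0.5);
    zero-depth or shallow SNPs stay unassigned.  When a per-cell long
    table (cell_id, chrom, pos, alt_count, depth) is given, the per-cell
    BAF matrix is returned with the bulk assignment retained as a
    column level.
    """
    phased: list[PhasedSNP] = []
    for _, row in bulk.iterrows():
        depth, alt = int(row["depth"]), int(row["alt_count"])
        if depth == 0 or depth < min_bulk_depth:
            phased.append(PhasedSNP(row["chrom"], int(row["pos"]),
                                    float("nan"), float("nan"), "unassigned"))
            continue
        baf = alt / depth
        p = stats.binomtest(alt, depth, 0.5).pvalue
        if p < p_threshold:
            assignment = "gained" if baf > 0.5 else "not_gained"
        else:
            assignment = "unassigned"
        phased.append(PhasedSNP(row["chrom"], int(row["pos"]), baf, p, assignment))
    baf_matrix = None
    if cells is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            cells = cells.assign(
                baf=cells["alt_count"] / cells["depth"].replace(0, np.nan)
            )
        baf_matrix = cells.pivot_table(
            index="cell_id", columns="pos", values="baf", aggfunc="first"
        )
        assign_by_pos = {s.position: s.allele_assignment for s in phased}
        baf_matrix.columns = pd.MultiIndex.from_tuples(
            [(p, assign_by_pos.get(p, "unassigned")) for p in baf_matrix.columns],
            names=["pos", "assignment"],
        )
    return phased, baf_matrix


def small_circle_content_groups(
    circles_by_cell: dict[str, list[CircleCall]],
    size_threshold: int = 3_000,
    group_frac: float = 0.4,
) -> pd.DataFrame:
    """Relative very-small-circle content and high/low/mid labels.

    Content = n(circles with length < ``size_threshold``) / n(circles).
    Cells ranked by content; top ``group_frac`` -> high, bottom -> low,
    remainder -> mid.  Ties break deterministically by cell id.
    Zero-circle cells are excluded with a warning.
    """
    rows = []
    for cell in sorted(circles_by_cell):
        classified = [c for c in circles_by_cell[cell] if c.classified]
        if not classified:
            warnings.warn(f"cell {cell!r} has no circles; excluded from grouping")
            continue
        n_small = sum(1 for c in classified if len(c.interval) < size_threshold)
        rows.append(dict(cell_id=cell, n_circles=len(classified),
                         content=n_small / len(classified)))
    if not rows:
        return pd.DataFrame(columns=["cell_id", "n_circles", "content", "group"])
    table = pd.DataFrame(rows)
    table = table.sort_values(["content", "cell_id"], kind="stable").reset_index(drop=True)
    n = len(table)
    k = int(n * group_frac)
    labels = np.array(["mid"] * n, dtype=object)
    labels[:k] = "low"
    if k > 0:
        labels[n - k :] = "high"
    table["group"] = labels
    return table.sort_values("cell_id").reset_index(drop=True)
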