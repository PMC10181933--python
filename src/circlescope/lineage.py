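"""mtDNA heteroplasmy lineage analysis.

Per-cell allele-count pileups are turned into variant calls by a minimal
threshold caller (the stand-in for the heavyweight somatic callers used
on real data), consensus-filtered in two steps -- a variant must be seen
in at least two cells by the same caller, and must then survive the
intersection of both callers -- and genotyped in every cell as an
allele-frequency matrix AF[x, b] = alt count / depth at position x.
Uninformative rows/columns are removed (cells with < 3 variants; variant
columns whose maximum AF < 5% or whose mean AF falls outside
(0.1%, 30%)), iterated to a fixpoint, and the cells are clustered by
complete-linkage hierarchical clustering on Euclidean distances between
AF vectors.  Missing AFs (depth 0) are imputed as zero for clustering
but recorded in a missingness mask; entries with AF >= 0.95 can be
flagged homoplasmic for cell-line genotyping with the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "VariantCall",
    "pileup_call",
    "consensus_filter",
    "build_af_matrix",
    "filter_af_matrix",
    "cluster_cells",
    "to_newick",
]

BASES = ("A", "C", "G", "T")
HOMOPLASMY_AF = 0.95


@dataclass(frozen=True)
class VariantCall:
    cell_id: str
    position: int
    ref: str
    alt: str
    af: float
    n_alt: int
    depth: int
    caller_tag: str = "pileup"


def pileup_call(
    pileup: pd.DataFrame,
    cell_id: str = "",
    min_af: float = 0.01,
    min_alt: int = 3,
    caller_tag: str = "pileup",
) -> list[VariantCall]:
    """Threshold caller on an allele-count table (pos, ref, A, C, G, T).

    An alternate allele is called when AF >= ``min_af`` and the alt count
    is >= ``min_alt``; depth-0 positions yield no call.
    """
    calls: list[VariantCall] = []
    for row in pileup.itertuples(index=False):
        depth = sum(getattr(row, b) for b in BASES)
        if depth == 0:
            continue
        for b in BASES:
            if b == row.ref:
                continue
            n_alt = getattr(row, b)
            af = n_alt / depth
            if af >= min_af and n_alt >= min_alt:
                calls.append(
                    VariantCall(cell_id, int(row.pos), row.ref, b, af, n_alt,
                                depth, caller_tag)
                )
    return calls


def consensus_filter(
    calls_a: list[VariantCall],
    calls_b: list[VariantCall],
    min_cells: int = 2,
) -> set[tuple[int, str]]:
    """Two-step consensus: per caller keep variants called in >=
    ``min_cells`` cells, then intersect the callers on (position, alt)."""

    def survivors(calls: list[VariantCall]) -> set[tuple[int, str]]:
        cells_per_variant: dict[tuple[int, str], set[str]] = {}
        for c in calls:
            cells_per_variant.setdefault((c.position, c.alt), set()).add(c.cell_id)
        return {v for v, cells in cells_per_variant.items() if len(cells) >= min_cells}

    return survivors(calls_a) & survivors(calls_b)


def build_af_matrix(
    pileups: dict[str, pd.DataFrame],
    variants: set[tuple[int, str]] | list[tuple[int, str]],
) -> pd.DataFrame:
    """Genotype every cell at every retained variant.

    AF = alt count / depth at the position; NaN where depth is zero.
    Columns are labelled ``pos:alt`` and sorted by position.
    """
    variants = sorted(variants)
    if not variants:
        raise ValueError("empty retained-variant set")
    columns = [f"{pos}:{alt}" for pos, alt in variants]
    cells = sorted(pileups)
    out = np.full((len(cells), len(variants)), np.nan)
    for ci, cell in enumerate(cells):
        table = pileups[cell].set_index("pos")
        for vi, (pos, alt) in enumerate(variants):
            if pos not in table.index:
                continue
            row = table.loc[pos]
            depth = int(sum(row[b] for b in BASES))
            if depth > 0:
                out[ci, vi] = row[alt] / depth
    return pd.DataFrame(out, index=cells, columns=columns)


def filter_af_matrix(
    matrix: pd.DataFrame,
    min_cell_variants: int = 3,
    min_col_max_af: float = 0.05,
    col_mean_af_bounds: tuple[float, float] = (0.001, 0.30),
) -> tuple[pd.DataFrame, list[str]]:
    """Drop uninformative variants and cells, iterating to a fixpoint.

    Variant columns fail when max AF < ``min_col_max_af`` or mean AF
    (over non-missing entries) falls outside ``col_mean_af_bounds``;
    cells fail with fewer than ``min_cell_variants`` non-missing,
    nonzero variants.  Returns the filtered matrix and a filter log.
    """
    m = matrix.copy()
    log: list[str] = []
    lo, hi = col_mean_af_bounds
    while True:
        col_max = m.max(axis=0, skipna=True)
        col_mean = m.mean(axis=0, skipna=True)
        bad_cols = m.columns[
            (col_max < min_col_max_af) | (col_mean > hi) | (col_mean < lo)
        ]
        if len(bad_cols):
            log.append(f"dropped {len(bad_cols)} variant column(s): "
                       + ",".join(map(str, bad_cols)))
            m = m.drop(columns=bad_cols)
        informative = ((m > 0) & m.notna()).sum(axis=1)
        bad_cells = m.index[informative < min_cell_variants]
        if len(bad_cells):
            log.append(f"dropped {len(bad_cells)} cell(s): "
                       + ",".join(map(str, bad_cells)))
            m = m.drop(index=bad_cells)
        if not len(bad_cols) and not len(bad_cells):
            break
        if m.empty:
            break
    if m.empty or m.shape[1] == 0:
        raise ValueError(
            "AF matrix empty after filtering; review thresholds "
            f"(log: {'; '.join(log) or 'nothing dropped'})"
        )
    return m, log


def cluster_cells(
    matrix: pd.DataFrame,
    n_clusters: int | None = None,
    metric: str = "euclidean",
    method: str = "complete",
):
    """Complete-linkage hierarchy on cell AF vectors.

    Missing entries are imputed as 0 (absence of support at high mtDNA
    depth ~ absence of the variant); the missingness mask is returned.
    Rows are ordered by cell id before linkage so ties resolve
    deterministically.  Returns (linkage matrix, labels Series or None,
    ordered cell ids, missingness mask).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 cells to cluster")
    m = matrix.sort_index()
    mask = m.isna()
    filled = m.fillna(0.0)
    link = hierarchy.linkage(pdist(filled.to_numpy(), metric=metric), method=method)
    labels = None
    if n_clusters is not None:
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
        labels = pd.Series(flat, index=m.index, name="clone")
    return link, labels, list(m.index), mask


def to_newick(link: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{node.dist + length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
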