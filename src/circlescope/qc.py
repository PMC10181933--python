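"""Cell-level quality control and expression normalization.

DNA quality uses mtDNA as the internal enrichment control: a cell passes
when its mean read depth over chrM is at least 10 reads per base pair
AND at least 85% of chrM positions are covered by >= 1 read.  Nuclei
carry no mtDNA, so the DNA rule is vacuous for them and filtering relies
on the RNA side alone.

RNA quality counts detected features after restricting to genes seen in
at least three cells, requiring >= 5,000 features for cell lines and
>= 2,000 for T cells and nuclei, and excluding cells with high
mitochondrial expression (> 15% in single cells, > 2.5% in nuclei).

Expression is normalized to transcripts per million (gene-length scaled,
columns summing to 1e6), then ln(1 + TPM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ReadRecord

__all__ = ["CellQC", "dna_qc", "rna_qc", "tpm_lognorm", "qc_table"]

SAMPLE_TYPES = ("cell_line", "t_cell", "nucleus")
MIN_FEATURES = {"cell_line": 5_000, "t_cell": 2_000, "nucleus": 2_000}
MAX_MITO_FRAC = {"cell_line": 0.15, "t_cell": 0.15, "nucleus": 0.025}


@dataclass
class CellQC:
    cell_id: str
    mean_mt_depth: float = float("nan")
    mt_bases_covered_frac: float = float("nan")
    n_features: int = 0
    mito_expr_frac: float = float("nan")
    pass_dna: bool = False
    pass_rna: bool = False


def dna_qc(
    reads: list[ReadRecord],
    chrm_length: int,
    sample_type: str = "cell_line",
    cell_id: str = "",
    min_depth: float = 10.0,
    min_covered_frac: float = 0.85,
    depth_cutoff: int = 1,
) -> CellQC:
    """DNA-side QC for one cell from its alignment records.

    Depth is total aligned bases on chrM divided by chrM length; covered
    fraction is the share of chrM positions with depth >= ``depth_cutoff``.
    Nuclei pass vacuously.
    """
    if sample_type not in SAMPLE_TYPES:
        raise ValueError(f"unknown sample_type {sample_type!r}")
    cov = np.zeros(chrm_length + 1, dtype=np.int64)
    aligned = 0
    for r in reads:
        if r.chrom != "chrM":
            continue
        lo, hi = max(0, r.start), min(chrm_length, r.end)
        if lo < hi:
            cov[lo] += 1
            cov[hi] -= 1
            aligned += hi - lo
    depth_profile = np.cumsum(cov[:-1])
    qc = CellQC(
        cell_id=cell_id,
        mean_mt_depth=aligned / chrm_length,
        mt_bases_covered_frac=float(np.mean(depth_profile >= depth_cutoff)),
    )
    if sample_type == "nucleus":
        qc.pass_dna = True
    else:
        qc.pass_dna = (
            qc.mean_mt_depth >= min_depth
            and qc.mt_bases_covered_frac >= min_covered_frac
        )
    return qc


def _is_mito_gene(name: str, chrom: str | None) -> bool:
    # annotation-dialect tolerant: chrM location or MT- prefix
    return (chrom == "chrM") or name.upper().startswith("MT-")


def rna_qc(
    counts: pd.DataFrame,
    sample_type: str,
    gene_chroms: dict[str, str] | None = None,
    min_cells_per_feature: int = 3,
    min_features: dict[str, int] | None = None,
    max_mito_frac: dict[str, float] | None = None,
) -> pd.DataFrame:
    """RNA-side QC flags for every cell (columns of ``counts``).

    Returns a frame indexed by cell with n_features, mito_expr_frac and
    pass_rna.  Feature counting happens after dropping genes detected in
    fewer than ``min_cells_per_feature`` cells; the mitochondrial
    fraction is computed on the full matrix.
    """
    if sample_type not in SAMPLE_TYPES:
        raise ValueError(f"unknown sample_type {sample_type!r}")
    min_features = min_features or MIN_FEATURES
    max_mito_frac = max_mito_frac or MAX_MITO_FRAC
    detected_cells = (counts > 0).sum(axis=1)
    kept = counts.loc[detected_cells >= min_cells_per_feature]
    n_features = (kept > 0).sum(axis=0)
    gene_chroms = gene_chroms or {}
    mito_mask = np.array(
        [_is_mito_gene(g, gene_chroms.get(g)) for g in counts.index]
    )
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = counts.loc[mito_mask].sum(axis=0) / totals
    passed = (n_features >= min_features[sample_type]) & ~(
        mito_frac > max_mito_frac[sample_type]
    )
    return pd.DataFrame(
        {
            "n_features": n_features,
            "mito_expr_frac": mito_frac,
            "pass_rna": passed,
        }
    )


def tpm_lognorm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """ln(1 + TPM) normalization.

    TPM_g = (c_g / L_g) / sum_g(c_g / L_g) * 1e6, per cell; all-zero
    cells stay all-zero (with a warning).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()][:3])
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpk = counts.div(lengths, axis=0)
    denom = rpk.sum(axis=0)
    if (denom == 0).any():
        warnings.warn("all-zero cell(s); emitting all-zero normalized columns")
    tpm = rpk.div(denom.replace(0, np.nan), axis=1) * 1e6
    return np.log1p(tpm.fillna(0.0))


def qc_table(dna: list[CellQC], rna: pd.DataFrame | None = None) -> pd.DataFrame:
    """Merge DNA and RNA QC into one row-per-cell report."""
    rows = {
        q.cell_id: dict(
            mean_mt_depth=q.mean_mt_depth,
            mt_bases_covered_frac=q.mt_bases_covered_frac,
            pass_dna=q.pass_dna,
        )
        for q in dna
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "cell_id"
    if rna is not None:
        table = table.join(rna, how="outer")
    return table.sort_index()
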