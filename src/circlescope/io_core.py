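"""Core genomic types, interval arithmetic and flat-file readers/writers.

Everything downstream of alignment speaks three currencies: 0-based
half-open :class:`GenomicInterval` regions, per-alignment
:class:`ReadRecord` objects with circle-evidence annotations (split-read
status, pair orientation), and fixed-bin :class:`SignalTrack` coverage
vectors.  On-disk formats follow the usual conventions: BED and bedGraph
are 0-based half-open, SAM text is 1-based and converted at the boundary
(pysam handles that), TSV matrices carry genes/positions as rows and
cells as columns.  Gzip is handled transparently by file suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenomicInterval",
    "ReadRecord",
    "SignalTrack",
    "parse_alignments",
    "overlap_query",
    "merge_intervals",
    "subtract_intervals",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

# MAPQ below this is dropped at parse time, uniformly across the pipeline.
DEFAULT_MIN_MAPQ = 5


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def validate_against(self, chrom_sizes: dict[str, int]) -> None:
        if self.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {self.chrom!r}")
        if self.end > chrom_sizes[self.chrom]:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {chrom_sizes[self.chrom]}"
            )


@dataclass
class ReadRecord:
    """One aligned read (or supplementary alignment piece).

    ``orientation`` is derived from SAM flags and mate coordinates:
    ``inward`` for a convergent (FR) pair, ``outward`` for a divergent
    (RF) pair -- the signature of a fragment spanning a circle junction
    -- ``same-strand`` when both mates map to the same strand, and
    ``unpaired`` otherwise.  Split reads (those carrying an SA tag, or
    supplementary pieces themselves) share a ``read_id``.
    """

    cell_id: str
    read_id: str
    chrom: str
    start: int
    end: int
    mapq: int
    is_split: bool = False
    is_supplementary: bool = False
    mate_chrom: str | None = None
    mate_start: int | None = None
    orientation: str = "unpaired"
    clip_side: str | None = None

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SignalTrack:
    """Fixed-bin signal vectors (e.g. CPM in 10-bp bins), one per chromosome.

    ``data[chrom][i]`` is the value of bin ``[i*bin_size, (i+1)*bin_size)``;
    bins tile each chromosome (the last bin may be partial).
    """

    bin_size: int
    data: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, values in self.data.items():
            if np.any(np.asarray(values) < 0):
                raise ValueError(f"negative signal values on {chrom}")

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], bin_size: int) -> "SignalTrack":
        data = {
            c: np.zeros(-(-length // bin_size)) for c, length in chrom_sizes.items()
        }
        return cls(bin_size=bin_size, data=data)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean signal over ``[start, end)``, weighting partial edge bins."""
        if chrom not in self.data:
            raise KeyError(f"track has no chromosome {chrom!r}")
        values = self.data[chrom]
        if end > len(values) * self.bin_size:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside track coverage"
            )
        lo, hi = start // self.bin_size, -(-end // self.bin_size)
        sub = values[lo:hi]
        weights = np.full(hi - lo, float(self.bin_size))
        weights[0] -= start - lo * self.bin_size
        if hi * self.bin_size > end:
            weights[-1] -= hi * self.bin_size - end
        return float(np.average(sub, weights=weights))


# ---------------------------------------------------------------------------
# alignment parsing


def _orientation(aln: pysam.AlignedSegment) -> str:
    if not aln.is_paired or aln.mate_is_unmapped or aln.next_reference_id < 0:
        return "unpaired"
    if aln.reference_id != aln.next_reference_id:
        return "unpaired"
    if aln.is_reverse == aln.mate_is_reverse:
        return "same-strand"
    if aln.is_reverse:
        fwd_start, rev_start = aln.next_reference_start, aln.reference_start
    else:
        fwd_start, rev_start = aln.reference_start, aln.next_reference_start
    # convergent (forward mate upstream of reverse mate) points inward
    return "inward" if fwd_start <= rev_start else "outward"


def _clip_side(aln: pysam.AlignedSegment) -> str | None:
    cigar = aln.cigartuples
    if not cigar:
        return None
    left = cigar[0][1] if cigar[0][0] in (4, 5) else 0
    right = cigar[-1][1] if cigar[-1][0] in (4, 5) else 0
    if left == right == 0:
        return None
    return "left" if left >= right else "right"


def parse_alignments(
    path,
    cell_id: str | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a SAM/BAM file.

    Secondary, duplicate-flagged, unmapped and MAPQ < ``min_mapq``
    records are dropped.  Supplementary alignments are kept (marked) so
    that both sides of a split read contribute positional evidence; they
    share the primary's ``read_id``.  ``cell_id`` defaults to the CB tag
    when present, else the file stem.
    """
    path = Path(path)
    default_cell = cell_id if cell_id is not None else path.name.split(".")[0]
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as handle:
        for aln in handle:
            if aln.is_unmapped:
                # htslib demotes records naming an unknown reference to
                # unmapped but leaves their CIGAR in place; a genuinely
                # unmapped read has none
                if aln.cigarstring:
                    raise ValueError(
                        f"record {aln.query_name!r} references a chromosome "
                        "absent from the header"
                    )
                continue
            if aln.is_secondary or aln.is_duplicate:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if aln.reference_id < 0 or aln.reference_name is None:
                raise ValueError(
                    f"record {aln.query_name!r} references an unknown chromosome"
                )
            cid = default_cell
            if cell_id is None and aln.has_tag("CB"):
                cid = str(aln.get_tag("CB"))
            yield ReadRecord(
                cell_id=cid,
                read_id=aln.query_name,
                chrom=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                mapq=aln.mapping_quality,
                is_split=aln.is_supplementary or aln.has_tag("SA"),
                is_supplementary=aln.is_supplementary,
                mate_chrom=(
                    handle.get_reference_name(aln.next_reference_id)
                    if aln.is_paired and aln.next_reference_id >= 0
                    else None
                ),
                mate_start=(
                    aln.next_reference_start
                    if aln.is_paired and aln.next_reference_id >= 0
                    else None
                ),
                orientation=_orientation(aln),
                clip_side=_clip_side(aln),
            )


# ---------------------------------------------------------------------------
# interval arithmetic


def overlap_query(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` overlapping ``b[j]``.

    Half-open semantics: ``[0, 10)`` does not overlap ``[10, 20)``.
    Sorted sweep over start/end events, O((|a|+|b|) log(|a|+|b|) + K).
    """
    events: list[tuple[str, int, int, int, int]] = []
    # (chrom, pos, kind, source, idx); kind 0 = removal, 1 = addition so
    # that at equal positions half-open touching intervals never co-occur
    for source, intervals in ((0, a), (1, b)):
        for idx, iv in enumerate(intervals):
            events.append((iv.chrom, iv.start, 1, source, idx))
            events.append((iv.chrom, iv.end, 0, source, idx))
    events.sort(key=lambda e: (e[0], e[1], e[2]))
    pairs: list[tuple[int, int]] = []
    active: tuple[set[int], set[int]] = (set(), set())
    current_chrom: str | None = None
    for chrom, _pos, kind, source, idx in events:
        if chrom != current_chrom:
            active = (set(), set())
            current_chrom = chrom
        if kind == 0:
            active[source].discard(idx)
        else:
            active[source].add(idx)
            others = active[1 - source]
            if source == 0:
                pairs.extend((idx, j) for j in others)
            else:
                pairs.extend((i, idx) for i in others)
    pairs.sort()
    return pairs


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals, merging any pair separated by <= ``gap`` bp."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + gap:
            out[-1].end = max(out[-1].end, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Parts of each interval in ``a`` not covered by any interval in ``b``."""
    b_merged = merge_intervals(b)
    out: list[GenomicInterval] = []
    for iv in a:
        cursor = iv.start
        for cut in (x for x in b_merged if x.chrom == iv.chrom):
            if cut.end <= cursor or cut.start >= iv.end:
                continue
            if cut.start > cursor:
                out.append(GenomicInterval(iv.chrom, cursor, cut.start, iv.name))
            cursor = max(cursor, cut.end)
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end, iv.name))
    return out


# ---------------------------------------------------------------------------
# flat files


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed chrom-sizes line")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with _open(path, "wt") as handle:
        for chrom, length in sizes.items():
            handle.write(f"{chrom}\t{length}\n")


def read_bed(path, chrom_sizes: dict[str, int] | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6; rejects malformed coordinates with the line number."""
    out: list[GenomicInterval] = []
    with _open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                iv = GenomicInterval(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3] if len(fields) > 3 else "",
                    float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if chrom_sizes is not None:
                try:
                    iv.validate_against(chrom_sizes)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, bed6: bool = True) -> None:
    with _open(path, "wt") as handle:
        for iv in intervals:
            if bed6:
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                    f"\t{iv.score:g}\t+\n"
                )
            else:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(
    path, chrom_sizes: dict[str, int], bin_size: int = 10
) -> SignalTrack:
    """Load a bedGraph into a fixed-bin :class:`SignalTrack`.

    Arbitrary bedGraph intervals are re-binned by coverage-weighted
    averaging; uncovered stretches contribute zero signal.
    """
    value_sum = {
        c: np.zeros(-(-length // bin_size)) for c, length in chrom_sizes.items()
    }
    with _open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if chrom not in value_sum:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not 0 <= start < end <= chrom_sizes[chrom]:
                raise ValueError(f"{path}:{lineno}: invalid coordinates")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative signal value")
            lo, hi = start // bin_size, -(-end // bin_size)
            for b in range(lo, hi):
                o = min(end, (b + 1) * bin_size) - max(start, b * bin_size)
                value_sum[chrom][b] += value * o
        data = {c: v / bin_size for c, v in value_sum.items()}
        for c, length in chrom_sizes.items():
            rem = length - (len(data[c]) - 1) * bin_size
            if 0 < rem < bin_size:
                data[c][-1] *= bin_size / rem
    return SignalTrack(bin_size=bin_size, data=data)


def write_bedgraph(track: SignalTrack, path, chrom_sizes: dict[str, int]) -> None:
    with _open(path, "wt") as handle:
        for chrom, values in track.data.items():
            length = chrom_sizes[chrom]
            for i, v in enumerate(values):
                start = i * track.bin_size
                end = min(start + track.bin_size, length)
                handle.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def read_counts_tsv(path) -> pd.DataFrame:
    """Count matrix TSV: rows = genes (or positions), columns = cells."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
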