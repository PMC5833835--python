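"""Genomic interval arithmetic, BED/TSV readers and writers, multiple-testing
correction and differential-expression labelling.

All coordinates are 0-based half-open throughout the package; BED files are
consumed and emitted natively in that convention.  Any 1-based input must be
converted at the boundary by the caller.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneRecord",
    "read_bed",
    "write_bed",
    "overlap_partition",
    "nearest_tss_distance",
    "bh_adjust",
    "classify_degs",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """floor((start + end) / 2); the point used for bin assignment and
        distance-to-TSS computations."""
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A BED-style feature with an aggregate enrichment signal."""

    interval: GenomicInterval
    name: str = ""
    signal: float = 0.0

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass
class GeneRecord:
    """One gene with its TSS and differential-expression status."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    log2fc: float = 0.0
    padj: float = 1.0
    expressed: bool = True
    de_status: str = "stable"  # one of {"up", "down", "stable"}

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must lie in [0, 1], got {self.padj}")
        if self.de_status not in ("up", "down", "stable"):
            raise ValueError(f"unknown de_status {self.de_status!r}")


def _as_interval(obj) -> GenomicInterval:
    return obj.interval if isinstance(obj, Peak) else obj


def read_bed(path) -> list[Peak]:
    """Read a 3-5 column BED file into a list of :class:`Peak`.

    Column 4 (if present) is the name, column 5 the signal.  Input order is
    preserved.  Malformed lines raise ``ValueError`` naming the line number.
    """
    peaks: list[Peak] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else ""
            try:
                signal = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric signal") from exc
            try:
                interval = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            peaks.append(Peak(interval, name=name, signal=signal))
    return peaks


def write_bed(records: Iterable[Peak | GenomicInterval], path) -> None:
    """Write intervals/peaks as 5-column BED (name and signal blank/0 for bare
    intervals).  Deterministic column order, input order preserved."""
    with open(path, "w") as handle:
        for rec in records:
            if isinstance(rec, Peak):
                iv, name, signal = rec.interval, rec.name, rec.signal
            else:
                iv, name, signal = rec, "", 0.0
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{signal:g}\n")


class _ChromIndex:
    """Per-chromosome sorted interval index supporting 'overlaps by >= k bp'."""

    def __init__(self, intervals: Sequence[GenomicInterval], k: int):
        self.k = k
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in grouped.items():
            ivs.sort(key=lambda x: x.start)
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            # prefix max of ends and prefix count of length >= k, start order
            long_enough = np.cumsum(ends - starts >= k)
            self.by_chrom[chrom] = (
                starts, np.maximum.accumulate(ends),
                np.concatenate([[0], long_enough]),
            )

    def has_overlap(self, iv: GenomicInterval) -> bool:
        """True iff some indexed interval overlaps ``iv`` by >= k bases.

        Case split on the target's start: targets starting at or before
        iv.start overlap by >= k iff their end reaches iv.start + k (and iv
        itself is >= k long); targets starting inside (iv.start, iv.end - k]
        overlap by >= k iff they are themselves >= k long.
        """
        k = self.k
        if iv.length < k:
            return False
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, prefix_max_end, prefix_long = entry
        i1 = np.searchsorted(starts, iv.start, side="right")
        if i1 > 0 and prefix_max_end[i1 - 1] >= iv.start + k:
            return True
        i2 = np.searchsorted(starts, iv.end - k, side="right")
        return prefix_long[i2] - prefix_long[i1] > 0


def overlap_partition(
    set_a: Sequence[Peak | GenomicInterval],
    set_b: Sequence[Peak | GenomicInterval],
    min_overlap: int = 1,
):
    """Partition two interval sets into common/specific by reciprocal overlap.

    An interval is *common* iff it overlaps at least one interval of the other
    set by ``min_overlap`` bases or more (half-open coordinates: adjacency is
    not overlap).  Returns ``(common_a, specific_a, common_b, specific_b)``,
    each preserving input order; the two partitions are exhaustive and
    disjoint per set.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    index_b = _ChromIndex([_as_interval(x) for x in set_b], min_overlap)
    index_a = _ChromIndex([_as_interval(x) for x in set_a], min_overlap)
    common_a = [x for x in set_a if index_b.has_overlap(_as_interval(x))]
    specific_a = [x for x in set_a if not index_b.has_overlap(_as_interval(x))]
    common_b = [x for x in set_b if index_a.has_overlap(_as_interval(x))]
    specific_b = [x for x in set_b if not index_a.has_overlap(_as_interval(x))]
    return common_a, specific_a, common_b, specific_b


def nearest_tss_distance(
    peaks: Sequence[Peak], genes: Sequence[GeneRecord]
) -> np.ndarray:
    """Absolute distance from each peak midpoint to the nearest TSS on the
    same chromosome.  Gene strand is ignored (the TSS is a point)."""
    tss_by_chrom: dict[str, np.ndarray] = {}
    for gene in genes:
        tss_by_chrom.setdefault(gene.chrom, [])  # type: ignore[arg-type]
        tss_by_chrom[gene.chrom].append(gene.tss)  # type: ignore[union-attr]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    missing = sorted({p.chrom for p in peaks} - set(tss_by_chrom))
    if missing:
        raise ValueError(
            "peaks on chromosome(s) without any gene: " + ", ".join(missing)
        )
    out = np.empty(len(peaks), dtype=np.int64)
    for i, peak in enumerate(peaks):
        tss = tss_by_chrom[peak.chrom]
        mid = peak.midpoint
        j = np.searchsorted(tss, mid)
        best = np.inf
        if j < len(tss):
            best = min(best, abs(int(tss[j]) - mid))
        if j > 0:
            best = min(best, abs(int(tss[j - 1]) - mid))
        out[i] = int(best)
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Ties in rank are broken by a stable sort on input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("all p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_degs(
    table: pd.DataFrame,
    lfc_threshold: float = 0.9,
    padj_threshold: float = 0.01,
) -> list[GeneRecord]:
    """Label genes up/down/stable from a differential-expression table.

    ``up`` iff log2fc > lfc_threshold and padj < padj_threshold (strict
    inequalities), ``down`` symmetric, else ``stable``.  The table must carry
    ``gene_id``, ``log2fc`` and ``padj`` columns; ``chrom``/``tss``/``strand``/
    ``expressed`` are carried through when present.
    """
    if lfc_threshold <= 0 or padj_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"gene table missing column(s): {sorted(missing)}")
    records = []
    for row in table.itertuples(index=False):
        log2fc = float(row.log2fc)
        padj = float(row.padj)
        if padj < padj_threshold and log2fc > lfc_threshold:
            status = "up"
        elif padj < padj_threshold and log2fc < -lfc_threshold:
            status = "down"
        else:
            status = "stable"
        records.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                chrom=str(getattr(row, "chrom", "chrUnknown")),
                tss=int(getattr(row, "tss", 0)),
                strand=str(getattr(row, "strand", "+")),
                log2fc=log2fc,
                padj=padj,
                expressed=bool(getattr(row, "expressed", True)),
                de_status=status,
            )
        )
    return records


def read_gene_table(path) -> pd.DataFrame:
    """Read a tab-separated gene/expression table with header."""
    table = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "padj"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return table


_GENE_COLUMNS = [
    "gene_id", "chrom", "tss", "strand", "log2fc", "padj", "expressed", "de_status",
]


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "tss": g.tss,
                "strand": g.strand,
                "log2fc": g.log2fc,
                "padj": g.padj,
                "expressed": g.expressed,
                "de_status": g.de_status,
            }
            for g in genes
        ],
        columns=_GENE_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
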