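"""Bridge-linker read processing and Hi-C pair classification.

The proximity-ligation protocol joins two blunt-ended genomic fragments via a
biotinylated bridge linker, so a sequencing read may run through the junction.
Reads are trimmed back to the 5' genomic fragment whenever a full linker copy
is found; aligned pairs are then de-duplicated and classified from span and
strand orientation into full segments (no ligation), self-ligations, and
intra-/inter-chromosomal ligations.  Short same-strand pairs are counted as
valid intra ligations: they require a ligation event, and only inward/outward
orientations mark the unligated/self-ligated artifacts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FORWARD_LINKER",
    "REVERSE_LINKER",
    "LinkerConfig",
    "TrimResult",
    "AlignedPair",
    "PairClass",
    "trim_linker",
    "dedupe",
    "estimate_span_threshold",
    "classify_pairs",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "classification_report",
]

FORWARD_LINKER = "CGCGATATCTTATCTGACT"
REVERSE_LINKER = "GTCAGATAAGATATCGCGT"


@dataclass(frozen=True)
class LinkerConfig:
    """Bridge-linker search settings.

    max_mismatches : allowed Hamming mismatches in a linker hit (default 0,
        exact match).
    min_fragment : shortest kept 5' fragment considered mappable (bp).
    """

    forward: str = FORWARD_LINKER
    reverse: str = REVERSE_LINKER
    max_mismatches: int = 0
    min_fragment: int = 20

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("linker sequences must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class TrimResult:
    sequence: str
    qualities: str | None
    linker_found: bool
    discarded: bool


class PairClass(str, Enum):
    FULL_SEGMENT = "full_segment"
    SELF_LIGATION = "self_ligation"
    INTRA = "intra"
    INTER = "inter"


@dataclass(frozen=True)
class AlignedPair:
    """One aligned read pair; positions are 0-based 5' mapping positions."""

    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str

    def __post_init__(self) -> None:
        for strand in (self.strand1, self.strand2):
            if strand not in ("+", "-"):
                raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def canonical(self) -> "AlignedPair":
        """Return the pair with (chrom1, pos1) <= (chrom2, pos2)."""
        if (self.chrom1, self.pos1) <= (self.chrom2, self.pos2):
            return self
        return AlignedPair(
            self.chrom2, self.pos2, self.strand2, self.chrom1, self.pos1, self.strand1
        )

    @property
    def span(self) -> int | None:
        if self.chrom1 != self.chrom2:
            return None
        return abs(self.pos2 - self.pos1)


def _find_linker(sequence: str, linker: str, max_mismatches: int) -> int:
    """Leftmost start of a full linker copy (<= max_mismatches), or -1."""
    if max_mismatches == 0:
        return sequence.find(linker)
    n, m = len(sequence), len(linker)
    if n < m:
        return -1
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    link = np.frombuffer(linker.encode(), dtype=np.uint8)
    for start in range(n - m + 1):
        if int(np.count_nonzero(seq[start : start + m] != link)) <= max_mismatches:
            return start
    return -1


def trim_linker(
    read: str,
    qualities: str | None = None,
    config: LinkerConfig | None = None,
) -> TrimResult:
    """Trim a read back to its 5' fragment at the first bridge-linker copy.

    The leftmost full linker occurrence in either orientation is used; later
    copies are irrelevant because only the 5' flank is retained.  A read with
    no linker passes through unchanged (``linker_found=False``).  Kept
    fragments shorter than ``min_fragment`` (including an empty 5' flank when
    the linker sits at the read start) are flagged ``discarded`` rather than
    raising.
    """
    if not read:
        raise ValueError("read must be non-empty")
    if qualities is not None and len(qualities) != len(read):
        raise ValueError("qualities must match read length")
    config = config or LinkerConfig()
    hits = [
        pos
        for pos in (
            _find_linker(read, config.forward, config.max_mismatches),
            _find_linker(read, config.reverse, config.max_mismatches),
        )
        if pos >= 0
    ]
    if not hits:
        return TrimResult(read, qualities, linker_found=False,
                          discarded=len(read) < config.min_fragment)
    cut = min(hits)
    kept = read[:cut]
    kept_q = qualities[:cut] if qualities is not None else None
    return TrimResult(kept, kept_q, linker_found=True,
                      discarded=len(kept) < config.min_fragment)


def dedupe(pairs: Iterable[AlignedPair]) -> list[AlignedPair]:
    """Collapse exact duplicates after canonical orientation; first kept."""
    seen: set[tuple] = set()
    out: list[AlignedPair] = []
    for pair in pairs:
        canon = pair.canonical()
        key = (canon.chrom1, canon.pos1, canon.strand1,
               canon.chrom2, canon.pos2, canon.strand2)
        if key not in seen:
            seen.add(key)
            out.append(canon)
    return out


def _orientation(pair: AlignedPair) -> str:
    """Orientation of a canonical intra-chromosomal pair."""
    p = pair.canonical()
    if p.strand1 == p.strand2:
        return "same_plus" if p.strand1 == "+" else "same_minus"
    return "inward" if p.strand1 == "+" else "outward"


def estimate_span_threshold(
    pairs: Sequence[AlignedPair],
    tolerance: float = 0.05,
    fallback: int = 3000,
    n_bins: int = 30,
    min_pairs_per_bin: int = 50,
) -> int:
    """Estimate the self-ligation span cut-off from strand orientations.

    True ligation products show all four strand orientations (++, +-, -+, --)
    in equal proportion at every span; unligated fragments (inward) and
    self-ligations (outward) inflate specific orientations at short spans.
    Spans are histogrammed in log-spaced bins and the left edge of the
    earliest bin from which all later well-populated bins have every
    orientation fraction within ``tolerance`` of 0.25 is returned.  With no
    intra-chromosomal pairs, or fewer than 1000, the fallback (~3 kb for a
    4-cutter) is returned with a warning.
    """
    intra = [p for p in pairs if p.chrom1 == p.chrom2]
    spans = np.array([p.span for p in intra], dtype=np.int64)
    mask = spans > 0
    if mask.sum() < 1000:
        warnings.warn(
            f"only {int(mask.sum())} intra-chromosomal pairs; "
            f"returning fallback threshold {fallback}",
            stacklevel=2,
        )
        return fallback
    spans = spans[mask]
    orients = np.array([_orientation(p) for p in intra])[mask]
    lo = max(spans.min(), 10)
    hi = spans.max() + 1
    edges = np.unique(np.geomspace(lo, hi, n_bins + 1).astype(np.int64))
    which = np.digitize(spans, edges) - 1
    labels = ("same_plus", "same_minus", "inward", "outward")
    balanced = np.zeros(len(edges) - 1, dtype=bool)
    populated = np.zeros(len(edges) - 1, dtype=bool)
    for b in range(len(edges) - 1):
        sel = which == b
        total = int(sel.sum())
        if total < min_pairs_per_bin:
            continue
        populated[b] = True
        fracs = np.array([(orients[sel] == lab).sum() / total for lab in labels])
        balanced[b] = bool(np.all(np.abs(fracs - 0.25) <= tolerance))
    # earliest bin from which every later populated bin is balanced
    ok_from = None
    for b in range(len(edges) - 1):
        later = populated[b:]
        if later.any() and np.all(balanced[b:][later]):
            ok_from = b
            break
    if ok_from is None:
        warnings.warn(
            "no span bin with balanced orientations; returning fallback",
            stacklevel=2,
        )
        return fallback
    return int(edges[ok_from])


def classify_pairs(
    pairs: Sequence[AlignedPair], threshold: int
) -> list[tuple[AlignedPair, PairClass]]:
    """Assign each pair exactly one class from span and strand orientation.

    Different chromosomes -> inter.  Same chromosome with span >= threshold
    -> intra.  Below the threshold the orientation decides: inward pairs are
    unligated full segments, outward pairs are self-ligations, same-strand
    pairs are kept as intra ligations.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = []
    for pair in pairs:
        canon = pair.canonical()
        if canon.chrom1 != canon.chrom2:
            cls = PairClass.INTER
        elif canon.span >= threshold:
            cls = PairClass.INTRA
        else:
            orient = _orientation(canon)
            if orient == "inward":
                cls = PairClass.FULL_SEGMENT
            elif orient == "outward":
                cls = PairClass.SELF_LIGATION
            else:
                cls = PairClass.INTRA
        out.append((canon, cls))
    return out


_PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def read_pairs_tsv(path) -> list[AlignedPair]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_PAIR_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        AlignedPair(r.chrom1, int(r.pos1), r.strand1, r.chrom2, int(r.pos2), r.strand2)
        for r in frame.itertuples(index=False)
    ]


def write_pairs_tsv(pairs: Sequence[AlignedPair], path) -> None:
    frame = pd.DataFrame(
        [(p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2) for p in pairs],
        columns=_PAIR_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def classification_report(
    classified: Sequence[tuple[AlignedPair, PairClass]]
) -> pd.DataFrame:
    """Per-class counts and fractions, mirroring library statistics tables."""
    counts = {cls.value: 0 for cls in PairClass}
    for _, cls in classified:
        counts[cls.value] += 1
    total = max(sum(counts.values()), 1)
    return pd.DataFrame(
        {
            "pair_class": list(counts),
            "count": list(counts.values()),
            "fraction": [c / total for c in counts.values()],
        }
    )
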