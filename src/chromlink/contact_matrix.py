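"""Binned Hi-C contact matrices: construction, ICE balancing, observed/expected
transforms and replicate reproducibility.

The native on-disk representation is a bin table TSV plus a sparse triplet
text file (bin1, bin2, count, upper triangle); in memory the genome-wide
matrix is dense, which is appropriate below a few thousand bins.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hic_pairs import AlignedPair, PairClass

__all__ = [
    "ContactMatrix",
    "make_bins",
    "bin_pairs_to_matrix",
    "ice_balance",
    "oe_transform",
    "replicate_correlation",
    "save_matrix",
    "load_matrix",
]


def make_bins(chromsizes: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    """Tile each chromosome with fixed-width bins (last bin may be short)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    rows = []
    for chrom, size in chromsizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins.index.name = "bin"
    return bins


@dataclass
class ContactMatrix:
    """Symmetric genome-wide binned contact matrix.

    counts[i, j] == counts[j, i] >= 0; ``weights`` are multiplicative per-bin
    balancing factors (NaN on masked bins) such that counts[i,j]*w[i]*w[j] has
    uniform coverage.
    """

    bins: pd.DataFrame
    counts: np.ndarray
    bin_size: int
    weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if self.weights is not None and len(self.weights) != n:
            raise ValueError("weights length must equal bin count")
        chroms = self.bins["chrom"].to_numpy()
        self._chrom_codes = pd.factorize(chroms)[0]

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero(self.bins["chrom"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(f"no bins for chromosome {chrom}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def intra_mask(self) -> np.ndarray:
        """Boolean matrix marking intra-chromosomal cells."""
        return self._chrom_codes[:, None] == self._chrom_codes[None, :]

    def intra_mass(self) -> float:
        """Total intra-chromosomal counts over i <= j (each pair once)."""
        intra = np.where(self.intra_mask(), self.counts, 0.0)
        return float(np.triu(intra).sum())

    def balanced_counts(self) -> np.ndarray:
        """counts * w_i * w_j, NaN on masked rows/columns."""
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run ice_balance")
        w = self.weights
        return self.counts * w[:, None] * w[None, :]

    def bin_of(self, chrom: str, pos: int) -> int:
        sl = self.chrom_slice(chrom)
        chrom_end = int(self.bins["end"].iloc[sl.stop - 1])
        if not (0 <= pos < chrom_end):
            raise ValueError(f"position {chrom}:{pos} beyond chromosome end")
        return sl.start + pos // self.bin_size


def bin_pairs_to_matrix(
    classified: Sequence[tuple[AlignedPair, PairClass]],
    chromsizes: Mapping[str, int],
    bin_size: int,
    classes_kept: frozenset = frozenset({PairClass.INTRA, PairClass.INTER}),
    metadata: dict | None = None,
) -> ContactMatrix:
    """Accumulate classified pairs into a symmetric binned count matrix.

    Full segments and self-ligations are artifacts and excluded by default;
    each kept pair increments its (bin1, bin2)/(bin2, bin1) cells once.
    """
    bins = make_bins(chromsizes, bin_size)
    n = len(bins)
    counts = np.zeros((n, n), dtype=np.int64)
    offsets = {}
    for chrom in chromsizes:
        sel = np.flatnonzero(bins["chrom"].to_numpy() == chrom)
        offsets[chrom] = int(sel[0])
    for pair, cls in classified:
        if cls not in classes_kept:
            continue
        for chrom, pos in ((pair.chrom1, pair.pos1), (pair.chrom2, pair.pos2)):
            if chrom not in chromsizes:
                raise ValueError(f"pair on unknown chromosome {chrom}: {pair}")
            if not (0 <= pos < chromsizes[chrom]):
                raise ValueError(f"position beyond chromosome end: {pair}")
        i = offsets[pair.chrom1] + pair.pos1 // bin_size
        j = offsets[pair.chrom2] + pair.pos2 // bin_size
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return ContactMatrix(bins, counts, bin_size, metadata=metadata or {})


def ice_balance(
    matrix: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    mask_low: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: per-bin weights equalizing row sums.

    Bins with zero coverage, plus the lowest-coverage ``mask_low`` fraction of
    the remainder, are masked (weight NaN).  Convergence when the maximum
    relative row-sum deviation over unmasked bins drops below ``tol``; the
    last iterate is returned with a warning otherwise.  Weights are scaled so
    the corrected matrix preserves total unmasked mass.
    """
    counts = matrix.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("cannot balance an all-zero matrix")
    n = matrix.n_bins
    coverage = counts.sum(axis=1)
    masked = coverage == 0
    n_extra = int(np.floor(mask_low * n))
    if n_extra > 0:
        alive = np.flatnonzero(~masked)
        order = alive[np.argsort(coverage[alive], kind="stable")]
        masked[order[:n_extra]] = True
    alive = ~masked
    if alive.sum() < 2:
        raise ValueError("fewer than 2 unmasked bins")

    work = counts[np.ix_(alive, alive)].copy()
    bias = np.ones(work.shape[0])
    converged = False
    for _ in range(max_iter):
        rowsum = work.sum(axis=1)
        mean = rowsum.mean()
        if mean == 0:
            raise ValueError("unmasked submatrix has zero mass")
        s = rowsum / mean
        if np.max(np.abs(s - 1.0)) < tol:
            converged = True
            break
        s[s == 0] = 1.0
        work /= np.outer(s, s)
        bias *= s
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations", stacklevel=2
        )
    weights_alive = 1.0 / bias
    # rescale so corrected total mass equals raw unmasked mass
    raw_mass = counts[np.ix_(alive, alive)].sum()
    corr_mass = (counts[np.ix_(alive, alive)]
                 * np.outer(weights_alive, weights_alive)).sum()
    weights_alive *= np.sqrt(raw_mass / corr_mass)
    weights = np.full(n, np.nan)
    weights[alive] = weights_alive
    return ContactMatrix(
        matrix.bins.copy(),
        matrix.counts,
        matrix.bin_size,
        weights=weights,
        metadata=dict(matrix.metadata),
    )


def oe_transform(matrix: ContactMatrix) -> np.ndarray:
    """Observed/expected transform of the balanced intra-chromosomal matrix.

    The expected value on each diagonal is the mean corrected count at that
    genomic distance over unmasked bins of the chromosome; inter-chromosomal
    and masked cells are NaN, as are diagonals with zero expected value.
    Scale-invariant: doubling all counts leaves the output unchanged.
    """
    corrected = (
        matrix.balanced_counts() if matrix.weights is not None
        else matrix.counts.astype(float)
    )
    n = matrix.n_bins
    out = np.full((n, n), np.nan)
    for chrom in matrix.chromosomes:
        sl = matrix.chrom_slice(chrom)
        block = corrected[sl, sl]
        m = block.shape[0]
        valid = ~np.isnan(block)
        if valid.any(axis=None) and np.count_nonzero(valid.any(axis=1)) < 2:
            raise ValueError(f"fewer than 2 unmasked bins on {chrom}")
        oe = np.full((m, m), np.nan)
        for d in range(m):
            diag = np.diagonal(block, offset=d)
            defined = ~np.isnan(diag)
            if not defined.any():
                continue
            expected = np.nanmean(diag)
            if expected == 0 or np.isnan(expected):
                continue
            vals = diag / expected
            idx = np.arange(m - d)
            oe[idx, idx + d] = vals
            oe[idx + d, idx] = vals
        out[sl, sl] = oe
    return out


def _coarsen(matrix: ContactMatrix, factor: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum counts into coarse bins of ``factor`` fine bins per chromosome.

    Returns (coarse counts, coarse chromosome codes).
    """
    blocks, codes = [], []
    for ci, chrom in enumerate(matrix.chromosomes):
        sl = matrix.chrom_slice(chrom)
        n = sl.stop - sl.start
        groups = np.arange(n) // factor
        codes.extend([ci] * (int(groups[-1]) + 1))
        blocks.append((sl, groups))
    n_coarse = len(codes)
    out = np.zeros((n_coarse, n_coarse))
    offs = np.cumsum([0] + [int(g[-1]) + 1 for _, g in blocks[:-1]])
    for (sl_a, g_a), off_a in zip(blocks, offs):
        for (sl_b, g_b), off_b in zip(blocks, offs):
            sub = matrix.counts[sl_a, sl_b]
            # two-stage group-sum
            tmp = np.zeros((int(g_a[-1]) + 1, sub.shape[1]))
            np.add.at(tmp, g_a, sub)
            block = np.zeros((tmp.shape[0], int(g_b[-1]) + 1))
            np.add.at(block.T, g_b, tmp.T)
            out[off_a : off_a + block.shape[0], off_b : off_b + block.shape[1]] = block
    return out, np.asarray(codes)


def replicate_correlation(
    m1: ContactMatrix, m2: ContactMatrix, coarsen_to: int = 1_000_000
) -> float:
    """Pearson correlation of log2(1+count) between two replicate matrices.

    Computed over intra-chromosomal upper-triangle cells after coarsening to
    ``coarsen_to`` resolution (megabase scale, as used for whole-genome
    reproducibility heatmaps).
    """
    if m1.counts.shape != m2.counts.shape or m1.bin_size != m2.bin_size:
        raise ValueError("matrices must share binning")
    if not m1.bins[["chrom", "start"]].equals(m2.bins[["chrom", "start"]]):
        raise ValueError("matrices must share bin tables")
    factor = max(1, coarsen_to // m1.bin_size)
    c1, codes = _coarsen(m1, factor)
    c2, _ = _coarsen(m2, factor)
    intra = codes[:, None] == codes[None, :]
    upper = np.triu(np.ones_like(c1, dtype=bool))
    sel = intra & upper
    x = np.log2(1.0 + c1[sel])
    y = np.log2(1.0 + c2[sel])
    return float(np.corrcoef(x, y)[0, 1])


def save_matrix(matrix: ContactMatrix, prefix) -> None:
    """Write ``<prefix>.bins.tsv`` and ``<prefix>.triplets.tsv`` (upper
    triangle, zero cells omitted)."""
    bins = matrix.bins.copy()
    if matrix.weights is not None:
        bins["weight"] = matrix.weights
    bins.to_csv(f"{prefix}.bins.tsv", sep="\t", index=True)
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu]
    nz = vals != 0
    trip = pd.DataFrame(
        {"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz]}
    )
    trip.to_csv(f"{prefix}.triplets.tsv", sep="\t", index=False)


def load_matrix(prefix, bin_size: int | None = None,
                metadata: dict | None = None) -> ContactMatrix:
    bins = pd.read_csv(f"{prefix}.bins.tsv", sep="\t", index_col=0)
    weights = None
    if "weight" in bins.columns:
        weights = bins.pop("weight").to_numpy()
    trip = pd.read_csv(f"{prefix}.triplets.tsv", sep="\t")
    n = len(bins)
    counts = np.zeros((n, n))
    b1 = trip["bin1"].to_numpy()
    b2 = trip["bin2"].to_numpy()
    val = trip["count"].to_numpy()
    counts[b1, b2] = val
    counts[b2, b1] = val
    if bin_size is None:
        bin_size = int((bins["end"] - bins["start"]).max())
    return ContactMatrix(bins, counts, bin_size, weights=weights,
                         metadata=metadata or {})
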