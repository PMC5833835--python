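"""Differential gene-regulatory (promoter-enhancer) interaction testing.

40-kb bins are annotated as gene regions (a promoter-mark peak at an
expressed gene's TSS) or regulatory regions (a distal acetylation peak away
from every promoter); within-TAD gene-regulatory bin pairs are the test
units.  Contacts are modelled as binomial sampling from each condition's
library: C_i ~ Binomial(n_i, p_i) with n_i the condition's total
intra-chromosomal Hi-C count.  On the MA plane, with X = log2 C2,
Y = log2 C1, M = X - Y and A = (X + Y)/2, the conditional law of M given
A = a is approximately normal under H0: p1 = p2.  The common proportion is
estimated as p_hat = 2^a / sqrt(n1 n2), giving delta-method variances
Var(log2 Ci) = (1 - p_hat) / (n_i p_hat ln^2 2); conditioning on A leaves

    E[M | A = a] = log2(n2 / n1),
    Var[M | A = a] = 4 Vx Vy / (Vx + Vy),

and z = (m - E[M|a]) / sqrt(Var[M|a]) is standard normal under H0.  M is
oriented condition2 - condition1, so a Gain (intensity enhanced after
treatment) has M > 0.  Benjamini-Hochberg-adjusted p < 0.001 defines
Gain/Loss calls.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contact_matrix import ContactMatrix
from .core_io import GeneRecord, Peak, bh_adjust

__all__ = [
    "BinAnnotation",
    "MarsInput",
    "MarsResult",
    "annotate_bins",
    "extract_candidate_pairs",
    "mars_test",
    "mars_test_arrays",
    "call_gain_loss",
]

LN2_SQ = np.log(2.0) ** 2


@dataclass
class MarsInput:
    """One gene-bin x regulatory-bin pair with pooled condition counts."""

    gene_bin: int
    reg_bin: int
    c1: float
    c2: float
    n1: float
    n2: float
    tad_id: int = -1

    def __post_init__(self) -> None:
        if self.gene_bin == self.reg_bin:
            raise ValueError("gene_bin and reg_bin must be distinct")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("total counts n1, n2 must be > 0")


@dataclass
class MarsResult:
    m: float
    a: float
    p1_hat: float
    p2_hat: float
    z: float
    p: float
    p_adj: float = np.nan
    call: str = "NS"


@dataclass
class BinAnnotation:
    bin: int
    gene_region: bool
    regulatory_region: bool
    linked_genes: tuple
    linked_peaks: tuple
    tad_id: int


def _bin_index_lookup(bins: pd.DataFrame):
    chrom_arr = bins["chrom"].to_numpy()
    offsets = {}
    sizes = {}
    for chrom in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        offsets[chrom] = int(sel[0])
        sizes[chrom] = int(bins["end"].iloc[sel[-1]])
    return offsets, sizes


def annotate_bins(
    bins: pd.DataFrame,
    promoter_peaks: Sequence[Peak],
    distal_peaks: Sequence[Peak],
    genes: Sequence[GeneRecord],
    tads: pd.DataFrame,
    bin_size: int = 40_000,
    promoter_window: int = 2_000,
) -> pd.DataFrame:
    """Label bins as gene and/or regulatory regions.

    gene_region: a promoter-mark peak midpoint within +/- promoter_window of
    an expressed gene's TSS puts the peak's bin in the gene-region set, with
    that gene linked.  regulatory_region: a distal-mark peak midpoint outside
    every expressed gene's promoter window marks its bin regulatory.
    ``tad_id`` is the TAD containing the bin midpoint (-1 if none).
    """
    offsets, sizes = _bin_index_lookup(bins)
    expressed = [g for g in genes if g.expressed]
    tss_by_chrom: dict[str, np.ndarray] = {}
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in expressed:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, gs in genes_by_chrom.items():
        gs.sort(key=lambda g: g.tss)
        tss_by_chrom[chrom] = np.array([g.tss for g in gs])

    def bin_of(chrom, pos):
        if chrom not in offsets or not (0 <= pos < sizes[chrom]):
            return None
        return offsets[chrom] + pos // bin_size

    def genes_near(chrom, pos, window):
        tss = tss_by_chrom.get(chrom)
        if tss is None:
            return []
        lo = np.searchsorted(tss, pos - window, side="left")
        hi = np.searchsorted(tss, pos + window, side="right")
        return genes_by_chrom[chrom][lo:hi]

    n = len(bins)
    gene_region = np.zeros(n, dtype=bool)
    regulatory_region = np.zeros(n, dtype=bool)
    linked_genes: list[set] = [set() for _ in range(n)]
    linked_peaks: list[set] = [set() for _ in range(n)]

    for peak in promoter_peaks:
        mid = peak.midpoint
        near = genes_near(peak.chrom, mid, promoter_window)
        if not near:
            continue
        b = bin_of(peak.chrom, mid)
        if b is None:
            continue
        gene_region[b] = True
        linked_genes[b].update(g.gene_id for g in near)
        linked_peaks[b].add(peak.name or f"{peak.chrom}:{peak.interval.start}")

    for peak in distal_peaks:
        mid = peak.midpoint
        if genes_near(peak.chrom, mid, promoter_window):
            continue  # inside a promoter spread: not a distal regulatory peak
        b = bin_of(peak.chrom, mid)
        if b is None:
            continue
        regulatory_region[b] = True
        linked_peaks[b].add(peak.name or f"{peak.chrom}:{peak.interval.start}")

    tad_id = np.full(n, -1, dtype=np.int64)
    mids = ((bins["start"] + bins["end"]) // 2).to_numpy()
    chrom_arr = bins["chrom"].to_numpy()
    for tad in tads.itertuples():
        sel = (chrom_arr == tad.chrom) & (mids >= tad.start) & (mids < tad.end)
        tad_id[sel] = tad.Index

    out = bins.copy()
    out["gene_region"] = gene_region
    out["regulatory_region"] = regulatory_region
    out["linked_genes"] = [tuple(sorted(s)) for s in linked_genes]
    out["linked_peaks"] = [tuple(sorted(s)) for s in linked_peaks]
    out["tad_id"] = tad_id
    return out


def extract_candidate_pairs(
    annotations: pd.DataFrame,
    cond1: Sequence[ContactMatrix],
    cond2: Sequence[ContactMatrix],
    min_total: int = 10,
) -> pd.DataFrame:
    """Within-TAD gene-region x regulatory-region pairs with pooled counts.

    Replicates are pooled per condition to improve accuracy; n1/n2 are the
    pooled total intra-chromosomal masses.  Ordered pairs with identical
    tad_id and distinct bin indices are kept; pairs with C1 + C2 below
    ``min_total`` are dropped (the normal approximation needs counts).
    """
    pooled1 = np.sum([m.counts for m in cond1], axis=0)
    pooled2 = np.sum([m.counts for m in cond2], axis=0)
    n1 = float(sum(m.intra_mass() for m in cond1))
    n2 = float(sum(m.intra_mass() for m in cond2))
    rows = []
    in_tad = annotations[annotations["tad_id"] >= 0]
    for tad_id, group in in_tad.groupby("tad_id", sort=True):
        gene_bins = group.index[group["gene_region"]].to_numpy()
        reg_bins = group.index[group["regulatory_region"]].to_numpy()
        for g in gene_bins:
            for r in reg_bins:
                if g == r:
                    continue
                c1 = float(pooled1[g, r])
                c2 = float(pooled2[g, r])
                if c1 + c2 < min_total:
                    continue
                rows.append((int(g), int(r), int(tad_id), c1, c2))
    if not rows:
        warnings.warn("no candidate gene-regulatory pairs", stacklevel=2)
    frame = pd.DataFrame(
        rows, columns=["gene_bin", "reg_bin", "tad_id", "c1", "c2"]
    )
    frame["n1"] = n1
    frame["n2"] = n2
    return frame


def mars_test_arrays(
    c1: np.ndarray, c2: np.ndarray, n1, n2
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MA-plot random-sampling test.

    Returns (M, A, z, p) with M = log2(c2) - log2(c1) (condition2 -
    condition1) and two-sided normal p-values.  Requires counts >= 1 and
    estimated sampling proportions strictly inside (0, 1).
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), c1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), c1.shape)
    if np.any(c1 < 1) or np.any(c2 < 1):
        raise ValueError("counts must be >= 1 (filter zero-count pairs upstream)")
    x = np.log2(c2)
    y = np.log2(c1)
    m = x - y
    a = (x + y) / 2.0
    p_hat = np.power(2.0, a) / np.sqrt(n1 * n2)
    if np.any(p_hat <= 0) or np.any(p_hat >= 1):
        raise ValueError("estimated proportion outside (0, 1): counts "
                         "inconsistent with totals")
    var1 = (1.0 - p_hat) / (n1 * p_hat * LN2_SQ)  # Var(log2 C1)
    var2 = (1.0 - p_hat) / (n2 * p_hat * LN2_SQ)  # Var(log2 C2)
    cond_mean = np.log2(n2 / n1)
    cond_var = 4.0 * var1 * var2 / (var1 + var2)
    z = (m - cond_mean) / np.sqrt(cond_var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return m, a, z, p


def mars_test(inp: MarsInput) -> MarsResult:
    """Scalar MA-plot random-sampling test for one gene-regulatory pair."""
    m, a, z, p = mars_test_arrays(
        np.array([inp.c1]), np.array([inp.c2]), inp.n1, inp.n2
    )
    p_hat = float(2.0 ** a[0] / np.sqrt(inp.n1 * inp.n2))
    return MarsResult(
        m=float(m[0]), a=float(a[0]), p1_hat=p_hat, p2_hat=p_hat,
        z=float(z[0]), p=float(p[0]),
    )


def call_gain_loss(
    candidates: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    threshold: float = 0.001,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Run the MA test on a candidate batch and call Gain/Loss interactions.

    Gain: BH-adjusted p < threshold and a higher condition-2 count
    proportion; Loss symmetric.  When bin annotations are supplied, the
    unique genes linked to the gene bins of each call set are returned.
    """
    out = candidates.copy()
    gene_lists: dict[str, list[str]] = {"Gain": [], "Loss": []}
    if len(out) == 0:
        for col in ("m", "a", "z", "p", "p_adj"):
            out[col] = np.array([], dtype=float)
        out["call"] = np.array([], dtype=object)
        return out, gene_lists
    m, a, z, p = mars_test_arrays(
        out["c1"].to_numpy(), out["c2"].to_numpy(),
        out["n1"].to_numpy(), out["n2"].to_numpy(),
    )
    p_adj = bh_adjust(p)
    prop1 = out["c1"].to_numpy() / out["n1"].to_numpy()
    prop2 = out["c2"].to_numpy() / out["n2"].to_numpy()
    call = np.full(len(out), "NS", dtype=object)
    call[(p_adj < threshold) & (prop2 > prop1)] = "Gain"
    call[(p_adj < threshold) & (prop2 < prop1)] = "Loss"
    out["m"], out["a"], out["z"], out["p"], out["p_adj"] = m, a, z, p, p_adj
    out["call"] = call
    if annotations is not None:
        for name in ("Gain", "Loss"):
            bins = out.loc[out["call"] == name, "gene_bin"].unique()
            genes: set[str] = set()
            for b in bins:
                genes.update(annotations["linked_genes"].loc[b])
            gene_lists[name] = sorted(genes)
    return out, gene_lists
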