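"""TAD-level interaction dynamics: internal/external count sums, the
replicate-derived empirical-null fold-change test, sigma-deviation categories,
DEG distribution across categories and boundary stability.

The differential test needs no parametric model: within-condition replicate
log2 ratios, pooled over both conditions and all TADs, form an empirical
background distribution of technical fold-change noise, and each
between-condition fold change earns a two-sided rank p-value from its
position in that background.  A TAD is significant only when every
replicate pairing is significant (p < alpha), mirroring the
"both replicates" rule.
"""
from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_matrix import ContactMatrix
from .core_io import GenomicInterval, GeneRecord

__all__ = [
    "tad_counts",
    "tad_foldchange_test",
    "sigma_categories",
    "deg_category_distribution",
    "assign_genes_to_tads",
    "boundary_stability",
    "tads_to_frame",
]

SIGMA_EDGES = (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0)


def tads_to_frame(tads: Sequence[GenomicInterval]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(t.chrom, t.start, t.end) for t in tads],
        columns=["chrom", "start", "end"],
    )
    frame.index.name = "tad_id"
    return frame


def _tad_bin_indices(matrix: ContactMatrix, tads: pd.DataFrame) -> list[np.ndarray]:
    """Bins belonging to each TAD (bin-midpoint containment)."""
    chrom_arr = matrix.bins["chrom"].to_numpy()
    mid = ((matrix.bins["start"] + matrix.bins["end"]) // 2).to_numpy()
    out = []
    for tad in tads.itertuples():
        sel = (chrom_arr == tad.chrom) & (mid >= tad.start) & (mid < tad.end)
        out.append(np.flatnonzero(sel))
    return out


def tad_counts(matrix: ContactMatrix, tads: pd.DataFrame) -> pd.DataFrame:
    """Raw internal and external interaction sums per TAD.

    internal: sum of counts over bin pairs i < j with both bins inside the TAD
    (bin self-contacts excluded — they are dominated by short-range
    artifacts).  external: intra-chromosomal cells with exactly one end in
    the TAD.  TADs narrower than 2 bins get internal = 0 with a warning.
    """
    overlapping = _check_tads_disjoint(tads)
    if overlapping:
        raise ValueError(f"TADs overlap within a chromosome: ids {overlapping}")
    internal = np.zeros(len(tads))
    external = np.zeros(len(tads))
    idx_list = _tad_bin_indices(matrix, tads)
    counts = matrix.counts
    for t, idx in enumerate(idx_list):
        if idx.size < 2:
            warnings.warn(
                f"TAD {t} covers fewer than 2 bins; internal set to 0",
                stacklevel=2,
            )
        chrom = tads["chrom"].iloc[t]
        sl = matrix.chrom_slice(chrom)
        block = counts[np.ix_(idx, idx)]
        diag = np.trace(block)
        internal[t] = (block.sum() - diag) / 2.0
        full = counts[np.ix_(idx, np.arange(sl.start, sl.stop))].sum()
        external[t] = full - 2.0 * internal[t] - diag
    out = tads.copy()
    out["internal"] = internal
    out["external"] = external
    return out


def _check_tads_disjoint(tads: pd.DataFrame) -> list[int]:
    bad = []
    for chrom, group in tads.groupby("chrom", sort=False):
        g = group.sort_values("start")
        ends = g["end"].to_numpy()[:-1]
        starts = g["start"].to_numpy()[1:]
        for k in np.flatnonzero(starts < ends):
            bad.append(int(g.index[k + 1]))
    return bad


def _normalized_counts(
    matrices: Sequence[ContactMatrix], tads: pd.DataFrame
) -> list[pd.DataFrame]:
    """Per-sample TAD counts rescaled to the mean intra-chromosomal mass.

    The common scale keeps the numbers on a count-like magnitude so the 0.5
    pseudocount used before log2 stays negligible for populated TADs.
    """
    masses = np.array([m.intra_mass() for m in matrices])
    if np.any(masses == 0):
        raise ValueError("a matrix has zero intra-chromosomal mass")
    target = masses.mean()
    frames = []
    for matrix, mass in zip(matrices, masses):
        frame = tad_counts(matrix, tads)
        frame[["internal", "external"]] *= target / mass
        frames.append(frame)
    return frames


def _empirical_two_sided_p(observed: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Rank-based two-sided p with add-one correction, in (0, 1]."""
    n = len(background)
    srt = np.sort(background)
    n_le = np.searchsorted(srt, observed, side="right")
    n_ge = n - np.searchsorted(srt, observed, side="left")
    p = (1.0 + 2.0 * np.minimum(n_le, n_ge)) / (n + 1.0)
    return np.minimum(p, 1.0)


def tad_foldchange_test(
    cond1: Sequence[ContactMatrix],
    cond2: Sequence[ContactMatrix],
    tads: pd.DataFrame,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Empirical-null differential test of TAD internal/external interactions.

    Background (per internal/external separately): log2 ratios between the
    replicates of each condition, pooled over both conditions and all TADs.
    Observed: log2(condition2 rep_k / condition1 rep_k) per TAD for each
    index-matched replicate pairing.  ``significant`` requires the INTERNAL
    p-value below ``alpha`` in every pairing.
    """
    if len(cond1) < 2 or len(cond2) < 2:
        raise ValueError("need at least 2 replicates per condition")
    n_rep = min(len(cond1), len(cond2))
    frames1 = _normalized_counts(list(cond1), tads)
    frames2 = _normalized_counts(list(cond2), tads)

    def logc(frame, col):
        return np.log2(frame[col].to_numpy() + pseudocount)

    out = tads.copy()
    results = {}
    for col in ("internal", "external"):
        background = np.concatenate(
            [logc(frames1[0], col) - logc(frames1[1], col),
             logc(frames2[0], col) - logc(frames2[1], col)]
        )
        pvals = []
        fcs = []
        for k in range(n_rep):
            obs = logc(frames2[k], col) - logc(frames1[k], col)
            fcs.append(obs)
            pvals.append(_empirical_two_sided_p(obs, background))
        results[col] = (np.mean(fcs, axis=0), np.stack(pvals))
    out["log2fc_internal"] = results["internal"][0]
    out["log2fc_external"] = results["external"][0]
    for k in range(n_rep):
        out[f"p_internal_rep{k + 1}"] = results["internal"][1][k]
        out[f"p_external_rep{k + 1}"] = results["external"][1][k]
    out["significant"] = np.all(results["internal"][1] < alpha, axis=0)
    return out


def sigma_categories(
    log2fc: Sequence[float], edges_in_sigma: Sequence[float] = SIGMA_EDGES
) -> np.ndarray:
    """Assign each TAD one of ``len(edges)+1`` categories by its deviation
    from the mean log2 fold change in standard-deviation units (1-based,
    category 1 the most decreased, the top category the most increased)."""
    values = np.asarray(log2fc, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 TADs")
    sigma = values.std()
    if sigma == 0:
        raise ValueError("zero standard deviation of fold changes")
    z = (values - values.mean()) / sigma
    return np.digitize(z, np.asarray(edges_in_sigma)) + 1


def assign_genes_to_tads(
    genes: Sequence[GeneRecord], tads: pd.DataFrame
) -> np.ndarray:
    """TAD id containing each gene's TSS, or -1 when outside all TADs."""
    out = np.full(len(genes), -1, dtype=np.int64)
    by_chrom = {
        chrom: group.sort_values("start")
        for chrom, group in tads.groupby("chrom", sort=False)
    }
    for i, gene in enumerate(genes):
        group = by_chrom.get(gene.chrom)
        if group is None:
            continue
        starts = group["start"].to_numpy()
        j = np.searchsorted(starts, gene.tss, side="right") - 1
        if j >= 0 and gene.tss < group["end"].iloc[j]:
            out[i] = group.index[j]
    return out


def deg_category_distribution(
    tad_tests: pd.DataFrame,
    genes: Sequence[GeneRecord],
    gene_tads: np.ndarray | None = None,
    n_categories: int = len(SIGMA_EDGES) + 1,
) -> pd.DataFrame:
    """Counts and within-category proportions of up/down/stable genes per
    sigma category, plus a ``total`` row over all TADs and a ``no_tad``
    bucket for genes whose TSS falls outside every TAD.

    ``tad_tests`` must carry a ``sigma_category`` column.
    """
    if "sigma_category" not in tad_tests.columns:
        raise ValueError("tad_tests must have a sigma_category column")
    if gene_tads is None:
        gene_tads = assign_genes_to_tads(genes, tad_tests)
    statuses = ("up", "down", "stable")
    rows = {}
    labels = [str(c) for c in range(1, n_categories + 1)] + ["total", "no_tad"]
    for lab in labels:
        rows[lab] = {f"n_{s}": 0 for s in statuses}
    cat_of_tad = tad_tests["sigma_category"]
    for gene, tad in zip(genes, gene_tads):
        if tad < 0:
            rows["no_tad"][f"n_{gene.de_status}"] += 1
            continue
        rows[str(int(cat_of_tad.loc[tad]))][f"n_{gene.de_status}"] += 1
        rows["total"][f"n_{gene.de_status}"] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index")
    totals = frame.sum(axis=1)
    for s in statuses:
        frame[f"prop_{s}"] = np.where(
            totals > 0, frame[f"n_{s}"] / totals.replace(0, np.nan), 0.0
        )
    frame.index.name = "category"
    return frame


def boundary_stability(
    tads1: pd.DataFrame,
    tads2: pd.DataFrame,
    tolerance: int = 40_000,
) -> tuple[float, pd.DataFrame]:
    """Fraction of set-1 TAD boundaries with a set-2 boundary within
    ``tolerance`` bp, plus the full distance-to-nearest table."""
    if len(tads1) == 0 or len(tads2) == 0:
        raise ValueError("TAD sets must be non-empty")

    def boundaries(tads):
        out = {}
        for chrom, group in tads.groupby("chrom", sort=False):
            out[chrom] = np.unique(
                np.concatenate([group["start"].to_numpy(), group["end"].to_numpy()])
            )
        return out

    b1, b2 = boundaries(tads1), boundaries(tads2)
    records = []
    for chrom, positions in b1.items():
        other = b2.get(chrom)
        for pos in positions:
            if other is None or other.size == 0:
                dist = np.inf
            else:
                j = np.searchsorted(other, pos)
                cands = []
                if j < other.size:
                    cands.append(abs(int(other[j]) - int(pos)))
                if j > 0:
                    cands.append(abs(int(other[j - 1]) - int(pos)))
                dist = min(cands)
            records.append((chrom, int(pos), dist))
    table = pd.DataFrame(records, columns=["chrom", "boundary", "distance"])
    fraction = float((table["distance"] <= tolerance).mean())
    return fraction, table
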