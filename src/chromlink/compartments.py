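"""A/B compartment calling from the first principal component of the
correlation-transformed intra-chromosomal contact matrix.

Per chromosome the balanced matrix is O/E-transformed, the Pearson
correlation matrix of bin contact profiles is formed, and the first principal
component of that correlation matrix assigns each bin a signed score.  The
eigenvector sign is arbitrary, so tracks are oriented against a per-bin
marker density (TSS density by default, active-mark peak density as an
alternative): the A compartment is gene-dense and carries positive scores
after orientation.  Compartment changes between conditions are called only
when every replicate of each condition agrees.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .contact_matrix import ContactMatrix, oe_transform

__all__ = [
    "CompartmentTrack",
    "pc1_track",
    "orient_and_label",
    "compartment_changes",
    "tss_density",
]

LABEL_A = "A"
LABEL_B = "B"
LABEL_UNDEFINED = "U"

CHANGE_CATEGORIES = ("unchanged", "A_to_B", "B_to_A", "undefined")


@dataclass
class CompartmentTrack:
    """Per-bin PC1 score and A/B/undefined label."""

    bins: pd.DataFrame
    pc1: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pc1) != len(self.bins) or len(self.label) != len(self.bins):
            raise ValueError("pc1/label length must equal bin count")


def _labels_from_pc1(pc1: np.ndarray) -> np.ndarray:
    label = np.full(len(pc1), LABEL_UNDEFINED, dtype=object)
    label[pc1 > 0] = LABEL_A
    label[pc1 < 0] = LABEL_B
    return label


def pc1_track(matrix: ContactMatrix) -> CompartmentTrack:
    """Unoriented first-principal-component track, one sign fit per chromosome.

    Masked bins (balancing weight NaN or zero-variance O/E profile) receive
    pc1 = 0 and the undefined label.
    """
    oe = oe_transform(matrix)
    n = matrix.n_bins
    pc1 = np.zeros(n)
    for chrom in matrix.chromosomes:
        sl = matrix.chrom_slice(chrom)
        block = oe[sl, sl]
        m = block.shape[0]
        defined = ~np.all(np.isnan(block), axis=1)
        if defined.sum() < 10:
            raise ValueError(
                f"chromosome {chrom}: fewer than 10 unmasked bins for PCA"
            )
        sub = block[np.ix_(defined, defined)]
        # remaining NaNs (zero-expected diagonals) -> neutral O/E of 1
        sub = np.where(np.isnan(sub), 1.0, sub)
        sd = sub.std(axis=1)
        informative = sd > 0
        if informative.sum() < 10:
            raise ValueError(f"chromosome {chrom}: degenerate (rank-0) matrix")
        prof = sub[np.ix_(informative, informative)]
        corr = np.corrcoef(prof)
        # PCA of the correlation matrix: leading eigenvector of the
        # covariance of its (column-centred) rows, scores per bin profile
        centred = corr - corr.mean(axis=0, keepdims=True)
        cov = centred.T @ centred
        eigvals, eigvecs = np.linalg.eigh(cov)
        if eigvals[-1] <= 0:
            raise ValueError(f"chromosome {chrom}: degenerate (rank-0) matrix")
        scores = centred @ eigvecs[:, -1]
        local = np.zeros(m)
        keep = np.flatnonzero(defined)[informative]
        local[keep] = scores
        pc1[sl] = local
    return CompartmentTrack(matrix.bins.copy(), pc1, _labels_from_pc1(pc1))


def tss_density(bins: pd.DataFrame, genes) -> np.ndarray:
    """Number of TSS per bin; the default orientation marker."""
    density = np.zeros(len(bins))
    chrom_arr = bins["chrom"].to_numpy()
    start_arr = bins["start"].to_numpy()
    end_arr = bins["end"].to_numpy()
    for gene in genes:
        sel = (chrom_arr == gene.chrom) & (start_arr <= gene.tss) & (gene.tss < end_arr)
        density[sel] += 1
    return density


def orient_and_label(
    track: CompartmentTrack, marker_density: np.ndarray
) -> CompartmentTrack:
    """Fix the eigenvector sign per chromosome against a marker density.

    The sign is flipped wherever the correlation between pc1 and the marker
    (over bins with nonzero pc1) is negative, so A (pc1 > 0) is the
    marker-dense, active compartment.
    """
    marker = np.asarray(marker_density, dtype=float)
    if len(marker) != len(track.bins):
        raise ValueError("marker density length must equal bin count")
    pc1 = track.pc1.copy()
    chrom_arr = track.bins["chrom"].to_numpy()
    for chrom in dict.fromkeys(chrom_arr):
        sel = chrom_arr == chrom
        defined = sel & (pc1 != 0)
        if defined.sum() == 0:
            continue
        m = marker[defined]
        if np.std(m) == 0:
            raise ValueError(
                f"chromosome {chrom}: zero-variance marker density"
            )
        r = np.corrcoef(pc1[defined], m)[0, 1]
        if r < 0:
            pc1[sel] = -pc1[sel]
    return CompartmentTrack(track.bins.copy(), pc1, _labels_from_pc1(pc1))


def compartment_changes(
    cond1_tracks: list[CompartmentTrack],
    cond2_tracks: list[CompartmentTrack],
) -> tuple[np.ndarray, dict[str, float]]:
    """Replicate-consistent per-bin compartment-switch classification.

    A bin is ``A_to_B`` only when every condition-1 replicate labels it A and
    every condition-2 replicate labels it B (``B_to_A`` symmetric); bins
    undefined in any replicate are ``undefined``; everything else is
    ``unchanged``.  Returns the per-bin category array and genome fractions
    (summing to 1 over all bins).
    """
    if not cond1_tracks or not cond2_tracks:
        raise ValueError("need at least one replicate track per condition")
    ref = cond1_tracks[0].bins
    for track in cond1_tracks + cond2_tracks:
        if not track.bins[["chrom", "start"]].equals(ref[["chrom", "start"]]):
            raise ValueError("bin tables differ between tracks")
    n = len(ref)
    l1 = np.stack([t.label for t in cond1_tracks])
    l2 = np.stack([t.label for t in cond2_tracks])
    any_undef = np.any(l1 == LABEL_UNDEFINED, axis=0) | np.any(
        l2 == LABEL_UNDEFINED, axis=0
    )
    all1_a = np.all(l1 == LABEL_A, axis=0)
    all1_b = np.all(l1 == LABEL_B, axis=0)
    all2_a = np.all(l2 == LABEL_A, axis=0)
    all2_b = np.all(l2 == LABEL_B, axis=0)
    cat = np.full(n, "unchanged", dtype=object)
    cat[all1_a & all2_b] = "A_to_B"
    cat[all1_b & all2_a] = "B_to_A"
    cat[any_undef] = "undefined"
    fractions = {c: float((cat == c).sum()) / n for c in CHANGE_CATEGORIES}
    return cat, fractions
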