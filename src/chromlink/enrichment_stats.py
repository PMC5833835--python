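"""Downstream enrichment statistics: Fisher exact tests, Mann-Whitney
comparisons, region signal fold changes, open-chromatin peak enrichment in
Gain/Loss regions, and network hub-degree ranking on a user-supplied
TF-target edge list.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneRecord, Peak

__all__ = [
    "ContingencyTable2x2",
    "fisher_enrichment",
    "mann_whitney",
    "region_signal_foldchange",
    "interaction_deg_enrichment",
    "peak_region_enrichment",
    "network_hub_degrees",
]

_ALTERNATIVES = {"greater": "greater", "less": "less", "two_sided": "two-sided"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows in-set/out-of-set, columns positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0:
                raise ValueError("contingency table entries must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_enrichment(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    alternative: str = "greater",
) -> tuple[float, float]:
    """Fisher's exact test; returns (odds ratio, p-value).

    Odds ratio is the sample (a*d)/(b*c) with infinity when b*c == 0 and
    a*d > 0, NaN when both products are zero.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = stats.fisher_exact(table.as_array(),
                              alternative=_ALTERNATIVES[alternative])
    ad, bc = table.a * table.d, table.b * table.c
    if bc > 0:
        odds = ad / bc
    else:
        odds = np.inf if ad > 0 else np.nan
    return float(odds), float(p)


def mann_whitney(
    group1: Sequence[float],
    group2: Sequence[float],
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Rank-sum Mann-Whitney U test; returns (U of group1, p-value).

    Exact null distribution when min(n1, n2) <= 8 and no ties; the
    tie-corrected normal approximation otherwise.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    has_ties = len(np.unique(np.concatenate([g1, g2]))) < g1.size + g2.size
    method = "exact" if (min(g1.size, g2.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative=_ALTERNATIVES[alternative],
                             method=method)
    return float(res.statistic), float(res.pvalue)


def region_signal_foldchange(
    signal1: np.ndarray,
    signal2: np.ndarray,
    regions: Sequence[Sequence[int]],
    eps: float = 0.5,
) -> np.ndarray:
    """Per-region log2((sum signal2 + eps) / (sum signal1 + eps)).

    ``regions`` are sequences of bin indices into the (depth-normalized)
    per-bin signal tracks.
    """
    s1 = np.asarray(signal1, dtype=float)
    s2 = np.asarray(signal2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("signal tracks must have the same length")
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        idx = np.asarray(region, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= s1.size):
            raise ValueError(f"region {i} outside signal domain")
        out[i] = np.log2((s2[idx].sum() + eps) / (s1[idx].sum() + eps))
    return out


def interaction_deg_enrichment(
    gain_genes: Iterable[str],
    loss_genes: Iterable[str],
    all_genes: Sequence[GeneRecord],
) -> dict[str, dict]:
    """DEG enrichment among genes involved in Gain/Loss interactions.

    For each call set (and their union), counts up/down/stable members and
    tests whether DEGs are over-represented relative to the remaining
    background genes (one-sided Fisher, ``greater``).
    """
    by_id = {g.gene_id: g for g in all_genes}
    sets = {
        "Gain": set(gain_genes),
        "Loss": set(loss_genes),
        "Gain_or_Loss": set(gain_genes) | set(loss_genes),
    }
    unknown = sorted(
        gid for s in sets.values() for gid in s if gid not in by_id
    )
    if unknown:
        raise ValueError(f"unknown gene id(s): {unknown}")
    n_total = len(all_genes)
    n_deg_total = sum(g.de_status != "stable" for g in all_genes)
    out = {}
    for name, members in sets.items():
        counts = {"up": 0, "down": 0, "stable": 0}
        for gid in members:
            counts[by_id[gid].de_status] += 1
        n_in = len(members)
        n_deg_in = counts["up"] + counts["down"]
        table = ContingencyTable2x2(
            a=n_deg_in,
            b=n_in - n_deg_in,
            c=n_deg_total - n_deg_in,
            d=(n_total - n_in) - (n_deg_total - n_deg_in),
        )
        odds, p = fisher_enrichment(table, alternative="greater")
        out[name] = {"counts": counts, "table": table, "odds_ratio": odds, "p": p}
    return out


def _bins_with_peak(peaks: Sequence[Peak], annotations: pd.DataFrame,
                    bin_size: int) -> set[int]:
    chrom_arr = annotations["chrom"].to_numpy()
    offsets = {}
    ends = {}
    for chrom in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        offsets[chrom] = int(annotations.index[sel[0]])
        ends[chrom] = int(annotations["end"].iloc[sel[-1]])
    hit = set()
    for peak in peaks:
        if peak.chrom not in offsets:
            continue
        mid = peak.midpoint
        if 0 <= mid < ends[peak.chrom]:
            hit.add(offsets[peak.chrom] + mid // bin_size)
    return hit


def peak_region_enrichment(
    cond1_specific: Sequence[Peak],
    cond2_specific: Sequence[Peak],
    annotations: pd.DataFrame,
    calls: pd.DataFrame,
    bin_size: int = 40_000,
) -> dict[str, dict]:
    """Condition-specific open-chromatin peak enrichment in Gain vs Loss bins.

    For gene regions and regulatory regions separately, builds the 2x2 table
    (bin of a Gain call vs of a Loss call) x (carries a condition-2-specific
    peak vs a condition-1-specific peak) and applies a one-sided Fisher test.
    Region sets with no calls are omitted with a warning.
    """
    hits1 = _bins_with_peak(cond1_specific, annotations, bin_size)
    hits2 = _bins_with_peak(cond2_specific, annotations, bin_size)
    out = {}
    for region_type, col in (("gene", "gene_bin"), ("regulatory", "reg_bin")):
        gain_bins = set(calls.loc[calls["call"] == "Gain", col])
        loss_bins = set(calls.loc[calls["call"] == "Loss", col])
        if not gain_bins or not loss_bins:
            warnings.warn(
                f"empty Gain or Loss call set for {region_type} regions; "
                "table omitted",
                stacklevel=2,
            )
            continue
        table = ContingencyTable2x2(
            a=len(gain_bins & hits2),
            b=len(gain_bins & hits1),
            c=len(loss_bins & hits2),
            d=len(loss_bins & hits1),
        )
        odds, p = fisher_enrichment(table, alternative="greater")
        out[region_type] = {"table": table, "odds_ratio": odds, "p": p}
    return out


def network_hub_degrees(
    edges: Iterable[tuple[str, str]],
    focus_nodes: Iterable[str],
) -> pd.DataFrame:
    """Total degree (in + out) of each focus node on the induced subnetwork.

    Duplicate edges collapse; the table is sorted by descending degree then
    node id (stable).  An induced subnetwork with no edges returns an empty
    table with a warning.
    """
    focus = set(focus_nodes)
    unique_edges = {
        (src, tgt) for src, tgt in edges if src in focus and tgt in focus
    }
    if not unique_edges:
        warnings.warn("induced subnetwork has no edges", stacklevel=2)
        return pd.DataFrame(columns=["node", "degree"])
    degree = {node: 0 for node in sorted(focus)}
    for src, tgt in unique_edges:
        degree[src] += 1
        degree[tgt] += 1
    frame = pd.DataFrame(
        sorted(degree.items()), columns=["node", "degree"]
    )
    frame = frame.sort_values(
        ["degree", "node"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return frame
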