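"""Synthetic toy chromatin system with planted ground truth.

The generator emulates the structure the analysis pipeline assumes: a small
genome tiled by non-overlapping TADs, a block-alternating A/B compartment
checkerboard, distance-decaying Poisson contact counts for two conditions and
two replicates, promoter/distal/open-chromatin peak sets with
condition-specific peaks, an expression table whose differential labels are
coupled to the planted interaction changes, and bridge-linker-bearing read
pairs with known classes.  Every downstream stage of the pipeline is thereby
testable against known truth without any external data.

Expected contact counts between intra-chromosomal bins i < j are

    E[c_ij] = scale * max(|i-j|, 1)^(-alpha)
              * tad_enrichment      (both bins in the same TAD)
              * compartment_affinity (same compartment label, per condition)
              * tad_boost^(+/-1)     (condition 2 only, boosted TADs)
              * planted_effect^(+/-1)(condition 2 only, planted pairs)

with a constant inter-chromosomal floor; counts are independent Poisson
draws per replicate.  All randomness flows from one seed via independent
named substreams, so every output is bit-reproducible.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import stats

from .contact_matrix import ContactMatrix, make_bins
from .core_io import GenomicInterval, Peak, bh_adjust
from .hic_pairs import FORWARD_LINKER, REVERSE_LINKER, AlignedPair

__all__ = [
    "TruthConfig",
    "TruthTables",
    "SimulatedMaps",
    "PeaksExpression",
    "ReadPairSim",
    "generate_truth",
    "simulate_contact_maps",
    "simulate_peaks_expression",
    "simulate_read_pairs",
    "truly_changed",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthConfig:
    """Configuration of the planted toy system.

    Defaults give 2 chromosomes x 20 Mb at 40-kb bins (500 bins each): large
    enough for >= 40 TADs of the ~400-kb scale seen in differentiated cells,
    small enough for seconds-scale simulation.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    bin_size: int = 40_000
    tad_size_range: tuple[int, int] = (240_000, 800_000)
    decay_exponent: float = 1.0        # alpha: contact decay ~ distance^-alpha
    tad_enrichment: float = 2.0        # within-TAD contact boost, all TADs
    tad_boost: float = 2.0             # beta: condition-2 multiplier, boosted TADs
    frac_boosted_tads: float = 0.0
    compartment_affinity: float = 2.0  # gamma: same-compartment boost
    compartment_block_bins: tuple[int, int] = (10, 25)
    frac_switch_ab: float = 0.01       # genome fraction flipped A->B in cond 2
    frac_switch_ba: float = 0.005
    planted_effect: float = 2.0        # delta: Gain fold change (1/delta Loss)
    n_planted_gain: int = 40
    n_planted_loss: int = 40
    planted_distance_bins: tuple[int, int] = (2, 4)  # enhancer-promoter span
    depth: float = 2_000_000.0         # expected total counts per replicate
    inter_floor: float = 0.005         # inter-chromosomal expected weight/cell
    n_replicates: int = 2
    gene_bin_fraction: float = 0.3
    reg_bin_fraction: float = 0.3
    gene_compartment_a_bias: float = 0.8
    planted_lfc: float = 2.0           # planted |log2 fold change| of expression
    expr_noise_sd: float = 0.3
    n_expr_reps: int = 4
    peak_coupling: float = 0.9         # P(planted pair gets a specific peak)
    background_specific: float = 0.05  # P(unplanted regulatory peak is specific)
    peak_width: int = 2_000
    promoter_window: int = 2_000

    def validate(self) -> None:
        if self.chrom_length % self.bin_size != 0:
            raise ValueError("bin_size must divide chrom_length")
        lo, hi = self.tad_size_range
        if lo < 2 * self.bin_size or hi < lo:
            raise ValueError("TAD sizes must span >= 2 bins with lo <= hi")
        for name in ("tad_enrichment", "tad_boost", "compartment_affinity",
                     "planted_effect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if not (0.0 <= self.frac_boosted_tads <= 1.0):
            raise ValueError("frac_boosted_tads must lie in [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")

    @property
    def chromsizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    @property
    def n_bins_per_chrom(self) -> int:
        return self.chrom_length // self.bin_size


@dataclass
class TruthTables:
    """Planted ground truth for one toy system."""

    config: TruthConfig
    bins: pd.DataFrame
    tads: pd.DataFrame            # chrom, start, end, boost in {up, down, neutral}
    tad_of_bin: np.ndarray
    comp_label1: np.ndarray       # per-bin 'A'/'B', condition 1
    comp_label2: np.ndarray
    genes: pd.DataFrame           # gene_id, chrom, tss, strand, bin, planted
    reg_bins: np.ndarray
    planted_pairs: pd.DataFrame   # gene_bin, reg_bin, tad_id, direction


@dataclass
class SimulatedMaps:
    matrices: dict[tuple[int, int], ContactMatrix]  # (condition, replicate)
    expected: dict[int, np.ndarray]                 # condition -> expected counts

    def condition(self, cond: int) -> list[ContactMatrix]:
        return [self.matrices[key] for key in sorted(self.matrices)
                if key[0] == cond]


@dataclass
class PeaksExpression:
    peaks: dict[tuple[str, int, int], list[Peak]]  # (mark, condition, replicate)
    expression: pd.DataFrame
    specific_reg_bins: dict[int, np.ndarray]       # condition -> reg bins with
                                                   # condition-specific peaks


@dataclass
class ReadPairSim:
    truth: pd.DataFrame
    aligned_pairs: list[AlignedPair]
    fastq1: Path | None = None
    fastq2: Path | None = None


def _rng(config: TruthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_truth(config: TruthConfig) -> TruthTables:
    """Draw the structural truth: TADs, compartments, genes, regulatory bins
    and planted gene-regulatory pairs.  Deterministic given the seed."""
    config.validate()
    rng = _rng(config, 0)
    bins = make_bins(config.chromsizes, config.bin_size)
    n_bins = len(bins)
    nb = config.n_bins_per_chrom
    lo_bins = config.tad_size_range[0] // config.bin_size
    hi_bins = config.tad_size_range[1] // config.bin_size

    # --- TADs tiling each chromosome ---
    tad_rows = []
    tad_of_bin = np.full(n_bins, -1, dtype=np.int64)
    for ci, chrom in enumerate(config.chromsizes):
        pos = 0
        while pos < nb:
            size = int(rng.integers(lo_bins, hi_bins + 1))
            end = min(pos + size, nb)
            if nb - end < lo_bins:  # absorb the remainder into this TAD
                end = nb
            tad_id = len(tad_rows)
            tad_rows.append(
                (chrom, pos * config.bin_size, end * config.bin_size)
            )
            tad_of_bin[ci * nb + pos : ci * nb + end] = tad_id
            pos = end
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])
    tads.index.name = "tad_id"
    n_tads = len(tads)
    boost = np.array(["neutral"] * n_tads, dtype=object)
    n_boosted = int(round(config.frac_boosted_tads * n_tads))
    if n_boosted:
        chosen = rng.choice(n_tads, size=n_boosted, replace=False)
        half = (n_boosted + 1) // 2
        boost[chosen[:half]] = "up"
        boost[chosen[half:]] = "down"
    tads["boost"] = boost

    # --- compartment checkerboard, per-condition labels ---
    lab1 = np.empty(n_bins, dtype=object)
    blo, bhi = config.compartment_block_bins
    for ci in range(config.n_chroms):
        current = rng.choice(["A", "B"])
        pos = 0
        while pos < nb:
            block = int(rng.integers(blo, bhi + 1))
            lab1[ci * nb + pos : ci * nb + min(pos + block, nb)] = current
            current = "B" if current == "A" else "A"
            pos += block
    lab2 = lab1.copy()
    n_ab = int(round(config.frac_switch_ab * n_bins))
    n_ba = int(round(config.frac_switch_ba * n_bins))
    a_bins = np.flatnonzero(lab1 == "A")
    b_bins = np.flatnonzero(lab1 == "B")
    if n_ab > len(a_bins) or n_ba > len(b_bins):
        raise ValueError("more compartment switches requested than source bins")
    if n_ab:
        lab2[rng.choice(a_bins, size=n_ab, replace=False)] = "B"
    if n_ba:
        lab2[rng.choice(b_bins, size=n_ba, replace=False)] = "A"

    # --- gene bins (A-biased) and regulatory bins ---
    n_gene = int(round(config.gene_bin_fraction * n_bins))
    n_reg = int(round(config.reg_bin_fraction * n_bins))
    if n_gene + n_reg > n_bins:
        raise ValueError("gene_bin_fraction + reg_bin_fraction exceeds 1")
    weight = np.where(lab1 == "A", config.gene_compartment_a_bias,
                      1.0 - config.gene_compartment_a_bias)
    weight = weight / weight.sum()
    gene_bins = np.sort(rng.choice(n_bins, size=n_gene, replace=False, p=weight))
    remaining = np.setdiff1d(np.arange(n_bins), gene_bins)
    reg_bins = np.sort(rng.choice(remaining, size=n_reg, replace=False))

    starts = bins["start"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    jitter = rng.integers(
        config.bin_size // 4, 3 * config.bin_size // 4, size=n_gene
    )
    strands = rng.choice(["+", "-"], size=n_gene)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{k:05d}" for k in range(n_gene)],
            "chrom": chroms[gene_bins],
            "tss": starts[gene_bins] + jitter,
            "strand": strands,
            "bin": gene_bins,
            "planted": "none",
        }
    )

    # --- planted within-TAD gene-regulatory pairs ---
    # Planted pairs emulate enhancer-promoter geometry: separations of a few
    # bins (80-160 kb at defaults), both ends in the same (active)
    # compartment and unswitched between conditions, within one TAD.
    n_wanted = config.n_planted_gain + config.n_planted_loss
    dmin, dmax = config.planted_distance_bins
    reg_set = set(int(b) for b in reg_bins)
    candidates = []
    for g in gene_bins:
        tid = tad_of_bin[g]
        same_tad = np.flatnonzero(tad_of_bin == tid)
        for r in same_tad:
            r = int(r)
            g_int = int(g)
            if (r in reg_set
                    and dmin <= abs(r - g_int) <= dmax
                    and lab1[g_int] == lab1[r]
                    and lab2[g_int] == lab1[g_int]
                    and lab2[r] == lab1[r]):
                candidates.append((g_int, r, int(tid)))
    rng.shuffle(candidates)
    used_g: set[int] = set()
    used_r: set[int] = set()
    planted = []
    for g, r, tid in candidates:
        if g in used_g or r in used_r:
            continue
        planted.append((g, r, tid))
        used_g.add(g)
        used_r.add(r)
        if len(planted) == n_wanted:
            break
    if len(planted) < n_wanted:
        raise ValueError(
            f"only {len(planted)} eligible within-TAD gene-regulatory pairs "
            f"with distinct bins; {n_wanted} planted pairs requested "
            "(constraint: pairs must lie within one TAD, bins >= 2 apart)"
        )
    directions = (["Gain"] * config.n_planted_gain
                  + ["Loss"] * config.n_planted_loss)
    planted_pairs = pd.DataFrame(
        [(g, r, t, d) for (g, r, t), d in zip(planted, directions)],
        columns=["gene_bin", "reg_bin", "tad_id", "direction"],
    )
    bin_to_dir = dict(zip(planted_pairs["gene_bin"],
                          planted_pairs["direction"]))
    genes["planted"] = [
        {"Gain": "gain", "Loss": "loss"}.get(bin_to_dir.get(int(b)), "none")
        for b in genes["bin"]
    ]
    return TruthTables(
        config=config,
        bins=bins,
        tads=tads,
        tad_of_bin=tad_of_bin,
        comp_label1=lab1,
        comp_label2=lab2,
        genes=genes,
        reg_bins=reg_bins,
        planted_pairs=planted_pairs,
    )


def _expected_weights(truth: TruthTables, condition: int) -> np.ndarray:
    config = truth.config
    n = len(truth.bins)
    codes = pd.factorize(truth.bins["chrom"])[0]
    within = np.arange(n) % config.n_bins_per_chrom
    same_chrom = codes[:, None] == codes[None, :]
    dist = np.abs(within[:, None] - within[None, :])
    decay = np.maximum(dist, 1).astype(float) ** (-config.decay_exponent)
    weight = np.where(same_chrom, decay, config.inter_floor)
    same_tad = truth.tad_of_bin[:, None] == truth.tad_of_bin[None, :]
    weight = np.where(same_tad, weight * config.tad_enrichment, weight)
    labels = truth.comp_label1 if condition == 1 else truth.comp_label2
    same_comp = (labels[:, None] == labels[None, :]) & same_chrom
    weight = np.where(same_comp, weight * config.compartment_affinity, weight)
    if condition == 2:
        boost_of_tad = truth.tads["boost"].to_numpy()
        for tid in np.flatnonzero(boost_of_tad != "neutral"):
            idx = np.flatnonzero(truth.tad_of_bin == tid)
            factor = (config.tad_boost if boost_of_tad[tid] == "up"
                      else 1.0 / config.tad_boost)
            weight[np.ix_(idx, idx)] *= factor
        for row in truth.planted_pairs.itertuples():
            factor = (config.planted_effect if row.direction == "Gain"
                      else 1.0 / config.planted_effect)
            weight[row.gene_bin, row.reg_bin] *= factor
            weight[row.reg_bin, row.gene_bin] *= factor
    return weight


def simulate_contact_maps(truth: TruthTables,
                          config: TruthConfig | None = None) -> SimulatedMaps:
    """Poisson contact maps for 2 conditions x n_replicates.

    Each condition's expected matrix is scaled so its upper-triangle total
    equals ``depth``; replicate counts are independent Poisson draws, so each
    replicate's realized total is within Poisson fluctuation of ``depth``.
    """
    config = config or truth.config
    rng = _rng(config, 1)
    n = len(truth.bins)
    iu = np.triu_indices(n)
    matrices: dict[tuple[int, int], ContactMatrix] = {}
    expected: dict[int, np.ndarray] = {}
    for cond in (1, 2):
        weight = _expected_weights(truth, cond)
        total = np.triu(weight).sum()
        scale = config.depth / total if config.depth > 0 else 0.0
        exp_counts = scale * weight
        expected[cond] = exp_counts
        for rep in range(1, config.n_replicates + 1):
            draws = rng.poisson(exp_counts[iu])
            counts = np.zeros((n, n), dtype=np.int64)
            counts[iu] = draws
            counts = counts + np.triu(counts, 1).T
            matrices[(cond, rep)] = ContactMatrix(
                truth.bins.copy(),
                counts,
                config.bin_size,
                metadata={"condition": cond, "replicate": rep},
            )
    return SimulatedMaps(matrices=matrices, expected=expected)


def truly_changed(sim: SimulatedMaps, rel_tol: float = 1e-9) -> np.ndarray:
    """Signed matrix of generator-level differential cells.

    +1 where the condition-2 expected count exceeds condition 1 (beyond
    ``rel_tol`` relative difference), -1 where lower, 0 elsewhere.  This is
    the full truth set for evaluating differential calls: it covers planted
    gene-regulatory pairs plus any cell altered by planted TAD boosts or
    compartment switches.
    """
    e1, e2 = sim.expected[1], sim.expected[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(e1 > 0, e2 / e1, 1.0)
    out = np.zeros(e1.shape, dtype=np.int8)
    out[ratio > 1 + rel_tol] = 1
    out[ratio < 1 - rel_tol] = -1
    return out


def simulate_peaks_expression(
    truth: TruthTables, config: TruthConfig | None = None
) -> PeaksExpression:
    """Peak sets (promoter / distal / open marks) and an expression table.

    Promoter-mark peaks sit at every expressed gene's TSS in all samples;
    distal-mark peaks sit at regulatory-bin midpoints, condition-specific at
    planted Gain (condition 2) and Loss (condition 1) regulatory bins with
    probability ``peak_coupling``.  Open-chromatin peaks mirror the distal
    placement plus common promoter peaks.  Each replicate adds a few private
    noise peaks, removed downstream by the replicate-intersection rule.
    Expression replicates are Gaussian on the log2 scale; the table carries
    t-test p-values with BH adjustment.
    """
    config = config or truth.config
    rng = _rng(config, 2)
    bins = truth.bins
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    chroms = bins["chrom"].to_numpy()
    half = config.peak_width // 2

    # planted specificity of regulatory bins
    specific: dict[int, int] = {}  # reg bin -> condition carrying the peak
    for row in truth.planted_pairs.itertuples():
        if rng.random() < config.peak_coupling:
            specific[int(row.reg_bin)] = 2 if row.direction == "Gain" else 1
    for b in truth.reg_bins:
        b = int(b)
        if b not in specific and rng.random() < config.background_specific:
            specific[b] = int(rng.choice([1, 2]))

    def make_peak(chrom, center, name, signal, rng):
        jitter = int(rng.integers(-50, 51))
        start = max(0, center - half + jitter)
        return Peak(GenomicInterval(chrom, start, start + config.peak_width),
                    name=name, signal=signal)

    peaks: dict[tuple[str, int, int], list[Peak]] = {
        (mark, cond, rep): []
        for mark in ("promoter", "distal", "open")
        for cond in (1, 2)
        for rep in range(1, config.n_replicates + 1)
    }

    # expression: planted log2 fold changes, replicate noise, t-test
    n_genes = len(truth.genes)
    base = rng.normal(5.0, 1.0, size=n_genes)
    lfc_map = {"gain": config.planted_lfc, "loss": -config.planted_lfc,
               "none": 0.0}
    true_lfc = np.array([lfc_map[p] for p in truth.genes["planted"]])
    reps1 = base[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(n_genes, config.n_expr_reps))
    reps2 = (base + true_lfc)[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(n_genes, config.n_expr_reps))
    log2fc = reps2.mean(axis=1) - reps1.mean(axis=1)
    pvals = stats.ttest_ind(reps2, reps1, axis=1).pvalue
    expression = truth.genes[["gene_id", "chrom", "tss", "strand"]].copy()
    expression["log2fc"] = log2fc
    expression["padj"] = bh_adjust(pvals)
    expression["expressed"] = True

    prom_signal = np.exp(rng.normal(3.0, 0.5, size=n_genes))
    for gi, gene in enumerate(truth.genes.itertuples()):
        for cond in (1, 2):
            signal = prom_signal[gi] * (2.0 ** log2fc[gi] if cond == 2 else 1.0)
            for rep in range(1, config.n_replicates + 1):
                peak = make_peak(gene.chrom, int(gene.tss),
                                 f"prom_{gene.gene_id}", signal, rng)
                peaks[("promoter", cond, rep)].append(peak)
                peaks[("open", cond, rep)].append(peak)

    reg_signal = np.exp(rng.normal(3.0, 0.5, size=len(truth.reg_bins)))
    for ri, b in enumerate(truth.reg_bins):
        b = int(b)
        center = int((starts[b] + ends[b]) // 2)
        conds = (specific[b],) if b in specific else (1, 2)
        for cond in conds:
            for rep in range(1, config.n_replicates + 1):
                peak = make_peak(chroms[b], center, f"reg_{b}",
                                 reg_signal[ri], rng)
                peaks[("distal", cond, rep)].append(peak)
                peaks[("open", cond, rep)].append(peak)

    # replicate-private noise peaks (do not survive intersection)
    n_noise = max(1, int(0.05 * len(truth.reg_bins)))
    chrom_names = list(config.chromsizes)
    for key in peaks:
        for k in range(n_noise):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            center = int(rng.integers(half, config.chrom_length - half))
            peaks[key].append(
                make_peak(chrom, center, f"noise_{key[0]}_{k}", 1.0, rng)
            )

    specific_reg = {
        cond: np.array(sorted(b for b, c in specific.items() if c == cond),
                       dtype=np.int64)
        for cond in (1, 2)
    }
    return PeaksExpression(peaks=peaks, expression=expression,
                           specific_reg_bins=specific_reg)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def simulate_read_pairs(
    truth: TruthTables,
    config: TruthConfig | None = None,
    n_pairs: int = 10_000,
    linker_prob: float = 1.0,
    class_probs: dict[str, float] | None = None,
    threshold: int = 3000,
    out_dir=None,
) -> ReadPairSim:
    """Read pairs with known classes plus bridge-linker-bearing sequences.

    Aligned coordinates are generated directly (bypassing alignment): class
    semantics fix span and strand orientation — self-ligations are outward
    pairs below the span threshold, full segments inward, intra ligations at
    or above it, inter ligations across chromosomes.  Each mate's sequence is
    a random 5' fragment, then (with probability ``linker_prob``) one full
    bridge-linker copy and a 3' fragment.  With ``out_dir`` set, gzipped
    FASTQ files are written byte-deterministically.
    """
    config = config or truth.config
    if n_pairs <= 0:
        raise ValueError("n_pairs must be > 0")
    rng = _rng(config, 3)
    probs = class_probs or {
        "intra": 0.55, "inter": 0.20, "self_ligation": 0.15,
        "full_segment": 0.10,
    }
    names = list(probs)
    pvals = np.array([probs[k] for k in names], dtype=float)
    pvals = pvals / pvals.sum()
    classes = rng.choice(names, size=n_pairs, p=pvals)
    chrom_names = list(config.chromsizes)
    size = config.chrom_length

    pairs: list[AlignedPair] = []
    rows = []
    reads1, reads2 = [], []
    for k in range(n_pairs):
        cls = classes[k]
        if cls == "inter":
            c1, c2 = rng.choice(len(chrom_names), size=2, replace=False)
            pos1 = int(rng.integers(0, size))
            pos2 = int(rng.integers(0, size))
            s1, s2 = rng.choice(["+", "-"], size=2)
            pair = AlignedPair(chrom_names[c1], pos1, s1,
                               chrom_names[c2], pos2, s2)
        else:
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            if cls == "intra":
                span = int(np.exp(rng.uniform(np.log(threshold),
                                              np.log(size / 4))))
                s1, s2 = rng.choice(["+", "-"], size=2)
            else:
                span = int(rng.integers(100, threshold))
                if cls == "full_segment":
                    s1, s2 = "+", "-"   # inward: upstream on +, downstream on -
                else:
                    s1, s2 = "-", "+"   # outward self-ligation
            pos1 = int(rng.integers(0, size - span))
            pair = AlignedPair(chrom, pos1, s1, chrom, pos1 + span, s2)
        pairs.append(pair)
        with_linker1 = rng.random() < linker_prob
        with_linker2 = rng.random() < linker_prob
        for target, with_linker in ((reads1, with_linker1),
                                    (reads2, with_linker2)):
            if with_linker:
                linker = (FORWARD_LINKER if rng.random() < 0.5
                          else REVERSE_LINKER)
                seq = (_random_seq(rng, int(rng.integers(30, 61))) + linker
                       + _random_seq(rng, int(rng.integers(20, 41))))
            else:
                seq = _random_seq(rng, 100)
            target.append(seq)
        rows.append(
            (f"pair{k:07d}", cls, pair.chrom1, pair.pos1, pair.strand1,
             pair.chrom2, pair.pos2, pair.strand2, with_linker1, with_linker2)
        )
    table = pd.DataFrame(
        rows,
        columns=["pair_id", "pair_class", "chrom1", "pos1", "strand1",
                 "chrom2", "pos2", "strand2", "linker_r1", "linker_r2"],
    )
    fq1 = fq2 = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fq1 = out_dir / "reads_R1.fastq.gz"
        fq2 = out_dir / "reads_R2.fastq.gz"
        for path, reads in ((fq1, reads1), (fq2, reads2)):
            with gzip.GzipFile(path, "wb", mtime=0) as handle:
                chunks = []
                for name, seq in zip(table["pair_id"], reads):
                    chunks.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
                handle.write("".join(chunks).encode())
    return ReadPairSim(truth=table, aligned_pairs=pairs, fastq1=fq1, fastq2=fq2)
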