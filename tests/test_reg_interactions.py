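"""Bin annotation, candidate extraction and the MA-plot random-sampling test."""
import numpy as np
import pandas as pd
import pytest

from chromlink.contact_matrix import ContactMatrix, make_bins
from chromlink.core_io import GeneRecord, GenomicInterval, Peak, classify_degs, overlap_partition
from chromlink.reg_interactions import (
    MarsInput,
    annotate_bins,
    call_gain_loss,
    extract_candidate_pairs,
    mars_test,
    mars_test_arrays,
)
from chromlink.synthetic_data import truly_changed
from chromlink.tad_dynamics import tads_to_frame

BIN = 40_000


def peak_at(center, name="p", width=2000):
    return Peak(GenomicInterval("chr1", center - width // 2, center + width // 2),
                name=name)


@pytest.fixture()
def simple_setup():
    bins = make_bins({"chr1": 20 * BIN}, BIN)
    genes = [GeneRecord("g1", "chr1", 100_000, expressed=True)]
    tads = tads_to_frame([GenomicInterval("chr1", 0, 20 * BIN)])
    return bins, genes, tads


class TestAnnotateBins:
    def test_promoter_peak_at_expressed_tss_marks_gene_region(self, simple_setup):
        bins, genes, tads = simple_setup
        ann = annotate_bins(bins, [peak_at(100_000)], [], genes, tads,
                            bin_size=BIN)
        assert ann["gene_region"].iloc[2]           # bin of position 100 kb
        assert ann["linked_genes"].iloc[2] == ("g1",)
        assert ann["gene_region"].sum() == 1

    def test_distal_peak_far_from_tss_marks_regulatory(self, simple_setup):
        bins, genes, tads = simple_setup
        ann = annotate_bins(bins, [], [peak_at(500_000)], genes, tads,
                            bin_size=BIN)
        assert ann["regulatory_region"].iloc[12]
        assert not ann["gene_region"].any()

    def test_distal_peak_inside_promoter_window_excluded(self, simple_setup):
        bins, genes, tads = simple_setup
        ann = annotate_bins(bins, [], [peak_at(100_500)], genes, tads,
                            bin_size=BIN)
        assert not ann["regulatory_region"].any()

    def test_promoter_peak_near_unexpressed_gene_ignored(self, simple_setup):
        bins, _, tads = simple_setup
        genes = [GeneRecord("g1", "chr1", 100_000, expressed=False)]
        ann = annotate_bins(bins, [peak_at(100_000)], [], genes, tads,
                            bin_size=BIN)
        assert not ann["gene_region"].any()

    def test_tad_assignment_by_bin_midpoint(self, simple_setup):
        bins, genes, _ = simple_setup
        tads = tads_to_frame([GenomicInterval("chr1", 0, 400_000),
                              GenomicInterval("chr1", 400_000, 800_000)])
        ann = annotate_bins(bins, [], [], genes, tads, bin_size=BIN)
        assert ann["tad_id"].iloc[9] == 0
        assert ann["tad_id"].iloc[10] == 1
        assert (ann["tad_id"].iloc[0:10] == 0).all()


def matrices_with_cell(bins, cells, base=20.0):
    n = len(bins)
    counts = np.full((n, n), base)
    for (i, j), v in cells.items():
        counts[i, j] = counts[j, i] = v
    return ContactMatrix(bins, counts, BIN)


class TestExtractCandidates:
    def build_annotations(self, bins, gene_bins, reg_bins, tad_ids):
        ann = bins.copy()
        ann["gene_region"] = [i in gene_bins for i in range(len(bins))]
        ann["regulatory_region"] = [i in reg_bins for i in range(len(bins))]
        ann["linked_genes"] = [() for _ in range(len(bins))]
        ann["linked_peaks"] = [() for _ in range(len(bins))]
        ann["tad_id"] = tad_ids
        return ann

    def test_within_tad_pair_kept_cross_tad_excluded(self):
        bins = make_bins({"chr1": 20 * BIN}, BIN)
        tad_ids = [0] * 10 + [1] * 10
        ann = self.build_annotations(bins, {2}, {5, 15}, tad_ids)
        m = matrices_with_cell(bins, {})
        cands = extract_candidate_pairs(ann, [m], [m])
        assert len(cands) == 1
        assert (cands.iloc[0]["gene_bin"], cands.iloc[0]["reg_bin"]) == (2, 5)

    def test_self_pair_excluded(self):
        bins = make_bins({"chr1": 20 * BIN}, BIN)
        ann = self.build_annotations(bins, {3}, {3}, [0] * 20)
        m = matrices_with_cell(bins, {})
        assert len(extract_candidate_pairs(ann, [m], [m])) == 0

    def test_minimum_count_filter(self):
        bins = make_bins({"chr1": 20 * BIN}, BIN)
        ann = self.build_annotations(bins, {2}, {5}, [0] * 20)
        low = matrices_with_cell(bins, {(2, 5): 2.0})
        cands = extract_candidate_pairs(ann, [low], [low], min_total=10)
        assert len(cands) == 0

    def test_replicates_pooled_and_totals_recorded(self):
        bins = make_bins({"chr1": 20 * BIN}, BIN)
        ann = self.build_annotations(bins, {2}, {5}, [0] * 20)
        m = matrices_with_cell(bins, {(2, 5): 30.0})
        cands = extract_candidate_pairs(ann, [m, m], [m], min_total=10)
        assert cands.iloc[0]["c1"] == 60.0 and cands.iloc[0]["c2"] == 30.0
        assert cands.iloc[0]["n1"] == pytest.approx(2 * m.intra_mass())


class TestMarsTest:
    def test_symmetric_null_gives_zero_z(self):
        res = mars_test(MarsInput(0, 1, c1=100, c2=100, n1=1e6, n2=1e6))
        assert res.m == 0 and res.z == 0 and res.p == pytest.approx(1.0)

    def test_twofold_change_example(self):
        # C2 doubled relative to C1 at equal depth: |z| ~ 5.8, p ~ 6e-9
        res = mars_test(MarsInput(0, 1, c1=100, c2=200, n1=1e6, n2=1e6))
        assert res.m == pytest.approx(1.0)
        assert res.z == pytest.approx(5.83, abs=0.05)
        assert res.p == pytest.approx(5.6e-9, rel=0.2)

    def test_depth_difference_explains_fold_change(self):
        # twice the condition-1 depth accounts for twice the count
        res = mars_test(MarsInput(0, 1, c1=200, c2=100, n1=2e6, n2=1e6))
        assert res.z == pytest.approx(0.0, abs=1e-12)

    def test_condition_swap_negates_z_preserves_p(self, rng):
        c1 = rng.integers(10, 500, 50).astype(float)
        c2 = rng.integers(10, 500, 50).astype(float)
        m1, a1, z1, p1 = mars_test_arrays(c1, c2, 1e6, 2e6)
        m2, a2, z2, p2 = mars_test_arrays(c2, c1, 2e6, 1e6)
        assert np.allclose(z1, -z2)
        assert np.allclose(p1, p2)
        assert np.allclose(a1, a2)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            mars_test_arrays(np.array([0.0]), np.array([5.0]), 1e6, 1e6)

    def test_inconsistent_totals_rejected(self):
        with pytest.raises(ValueError, match="proportion"):
            mars_test_arrays(np.array([1100.0]), np.array([1100.0]), 1e3, 1e3)

    def test_monte_carlo_conditional_moments(self, rng):
        """Delta-method conditional mean/variance vs binomial simulation."""
        c1, c2, n1, n2 = 600, 600, 1e6, 1e6
        a_obs = (np.log2(c1) + np.log2(c2)) / 2
        p_hat = 2.0 ** a_obs / np.sqrt(n1 * n2)
        ln2sq = np.log(2.0) ** 2
        v1 = (1 - p_hat) / (n1 * p_hat * ln2sq)
        v2 = (1 - p_hat) / (n2 * p_hat * ln2sq)
        tau2 = 4 * v1 * v2 / (v1 + v2)
        draws1 = rng.binomial(int(n1), p_hat, size=400_000)
        draws2 = rng.binomial(int(n2), p_hat, size=400_000)
        a = (np.log2(draws1) + np.log2(draws2)) / 2
        m = np.log2(draws2) - np.log2(draws1)
        sel = np.abs(a - a_obs) < 0.05
        mc_mean = m[sel].mean()
        mc_var = m[sel].var(ddof=1)
        assert abs(mc_mean) < 3 * m[sel].std() / np.sqrt(sel.sum())
        assert abs(mc_var - tau2) / tau2 < 0.02


class TestCallGainLoss:
    def make_batch(self, pvals_like):
        """Candidates engineered to produce the requested significance."""
        rows = []
        for i, (c1, c2) in enumerate(pvals_like):
            rows.append((2 * i, 2 * i + 1, 0, c1, c2))
        frame = pd.DataFrame(rows, columns=["gene_bin", "reg_bin", "tad_id",
                                            "c1", "c2"])
        frame["n1"] = 1e6
        frame["n2"] = 1e6
        return frame

    def test_null_batch_all_ns(self):
        calls, gene_lists = call_gain_loss(self.make_batch([(100, 101)] * 20))
        assert (calls["call"] == "NS").all()
        assert gene_lists == {"Gain": [], "Loss": []}

    def test_single_strong_pair_called_with_direction(self):
        calls, _ = call_gain_loss(self.make_batch([(100, 300)]))
        assert calls["call"].iloc[0] == "Gain"
        calls, _ = call_gain_loss(self.make_batch([(300, 100)]))
        assert calls["call"].iloc[0] == "Loss"

    def test_adjusted_p_is_bh_over_batch(self):
        batch = self.make_batch([(100, 300), (100, 100), (100, 101), (98, 100)])
        calls, _ = call_gain_loss(batch)
        from chromlink.core_io import bh_adjust

        assert np.allclose(calls["p_adj"], bh_adjust(calls["p"]))

    def test_empty_input(self):
        calls, gene_lists = call_gain_loss(self.make_batch([]))
        assert len(calls) == 0 and gene_lists == {"Gain": [], "Loss": []}


@pytest.fixture(scope="module")
def pipeline(default_truth, default_maps, default_peaks_expression):
    pe = default_peaks_expression

    def convincing(mark, cond):
        common, *_ = overlap_partition(
            pe.peaks[(mark, cond, 1)], pe.peaks[(mark, cond, 2)]
        )
        return common

    promoter = convincing("promoter", 1) + convincing("promoter", 2)
    distal = convincing("distal", 1) + convincing("distal", 2)
    genes = classify_degs(pe.expression)
    ann = annotate_bins(default_truth.bins, promoter, distal, genes,
                        default_truth.tads, bin_size=BIN)
    cands = extract_candidate_pairs(
        ann, default_maps.condition(1), default_maps.condition(2)
    )
    calls, gene_lists = call_gain_loss(cands, ann)
    return ann, calls, gene_lists


class TestPlantedRecovery:
    """Full pipeline on the default planted system."""

    def test_no_candidate_spans_a_tad_boundary(self, pipeline, default_truth):
        _, calls, _ = pipeline
        tad_of = default_truth.tad_of_bin
        assert (tad_of[calls["gene_bin"]] == tad_of[calls["reg_bin"]]).all()

    def test_recall_of_planted_pairs(self, pipeline, default_truth):
        _, calls, _ = pipeline
        called = {
            (r.gene_bin, r.reg_bin): r.call
            for r in calls[calls["call"] != "NS"].itertuples()
        }
        hits = [
            called.get((row.gene_bin, row.reg_bin)) == row.direction
            for row in default_truth.planted_pairs.itertuples()
        ]
        assert np.mean(hits) >= 0.8

    def test_precision_against_generator_truth(self, pipeline, default_maps):
        _, calls, _ = pipeline
        changed = truly_changed(default_maps)
        called = calls[calls["call"] != "NS"]
        correct = [
            changed[r.gene_bin, r.reg_bin] == (1 if r.call == "Gain" else -1)
            for r in called.itertuples()
        ]
        assert len(called) > 0
        assert np.mean(correct) >= 0.9

    def test_gain_genes_enriched_for_upregulation(self, pipeline,
                                                  default_peaks_expression):
        _, _, gene_lists = pipeline
        expr = default_peaks_expression.expression.set_index("gene_id")
        gain_lfc = expr.loc[gene_lists["Gain"], "log2fc"]
        loss_lfc = expr.loc[gene_lists["Loss"], "log2fc"]
        assert gain_lfc.mean() > 1.0
        assert loss_lfc.mean() < -1.0
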