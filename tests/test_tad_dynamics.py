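"""TAD counting, empirical-null fold-change test, sigma categories,
DEG distribution and boundary stability."""
import numpy as np
import pandas as pd
import pytest

from chromlink.contact_matrix import ContactMatrix, make_bins
from chromlink.core_io import GeneRecord
from chromlink.synthetic_data import TruthConfig, generate_truth, simulate_contact_maps
from chromlink.tad_dynamics import (
    _empirical_two_sided_p,
    assign_genes_to_tads,
    boundary_stability,
    deg_category_distribution,
    sigma_categories,
    tad_counts,
    tad_foldchange_test,
    tads_to_frame,
)
from chromlink.core_io import GenomicInterval


def ones_matrix(n=10, bin_size=10):
    bins = make_bins({"chr1": n * bin_size}, bin_size)
    return ContactMatrix(bins, np.ones((n, n)), bin_size)


def frame(*rows):
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out.index.name = "tad_id"
    return out


class TestTadCounts:
    def test_three_bin_tad_on_all_ones(self):
        m = ones_matrix()
        tads = frame(("chr1", 0, 30))
        res = tad_counts(m, tads)
        # pairs (0,1), (0,2), (1,2), diagonal excluded
        assert res["internal"].iloc[0] == 3

    def test_whole_chromosome_tad_has_no_external(self):
        m = ones_matrix()
        tads = frame(("chr1", 0, 100))
        res = tad_counts(m, tads)
        assert res["external"].iloc[0] == 0

    def test_internal_external_outside_mass_conservation(self, rng):
        n = 20
        counts = rng.poisson(5.0, size=(n, n)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = ContactMatrix(make_bins({"chr1": n * 10}, 10), counts, 10)
        tads = frame(("chr1", 0, 80), ("chr1", 80, 150))
        res = tad_counts(m, tads)
        total = np.triu(counts, 1).sum()
        internal = res["internal"].sum()
        external = res["external"].sum() / 1.0
        # remaining mass: pairs between the two TADs or involving bins 15+
        # external counts each boundary-crossing cell once per owning TAD
        outside_idx = np.arange(15, 20)
        t1 = np.arange(0, 8)
        t2 = np.arange(8, 15)
        cross_t1_t2 = counts[np.ix_(t1, t2)].sum()
        cross_out = (counts[np.ix_(np.concatenate([t1, t2]), outside_idx)].sum()
                     + np.triu(counts[np.ix_(outside_idx, outside_idx)], 1).sum())
        assert internal + cross_t1_t2 + cross_out == pytest.approx(total)

    def test_overlapping_tads_rejected(self):
        m = ones_matrix()
        tads = frame(("chr1", 0, 50), ("chr1", 40, 90))
        with pytest.raises(ValueError, match="overlap"):
            tad_counts(m, tads)

    def test_single_bin_tad_warns_zero_internal(self):
        m = ones_matrix()
        tads = frame(("chr1", 0, 10))
        with pytest.warns(UserWarning):
            res = tad_counts(m, tads)
        assert res["internal"].iloc[0] == 0


class TestEmpiricalP:
    def test_central_observation_has_p_near_one(self, rng):
        background = rng.normal(0, 1, 999)
        p = _empirical_two_sided_p(np.array([np.median(background)]), background)
        assert p[0] > 0.9

    def test_extreme_observation_rank_formula(self, rng):
        background = rng.normal(0, 1, 999)
        p = _empirical_two_sided_p(np.array([100.0]), background)
        assert p[0] == pytest.approx(1 / 1000)

    def test_p_in_unit_interval(self, rng):
        background = rng.normal(0, 1, 500)
        obs = rng.normal(0, 2, 100)
        p = _empirical_two_sided_p(obs, background)
        assert np.all((p > 0) & (p <= 1))


class TestFoldchangeTest:
    def test_null_calibration(self):
        config = TruthConfig(seed=3, frac_boosted_tads=0.0, n_planted_gain=0,
                             n_planted_loss=0, frac_switch_ab=0.0,
                             frac_switch_ba=0.0)
        truth = generate_truth(config)
        sim = simulate_contact_maps(truth)
        res = tad_foldchange_test(sim.condition(1), sim.condition(2),
                                  truth.tads)
        assert res["significant"].mean() <= 0.05

    def test_boosted_tads_recovered(self):
        config = TruthConfig(seed=3, frac_boosted_tads=0.2, tad_boost=2.0)
        truth = generate_truth(config)
        sim = simulate_contact_maps(truth)
        res = tad_foldchange_test(sim.condition(1), sim.condition(2),
                                  truth.tads)
        boosted = (truth.tads["boost"] != "neutral").to_numpy()
        assert res.loc[boosted, "significant"].mean() >= 0.9
        up = (truth.tads["boost"] == "up").to_numpy()
        down = (truth.tads["boost"] == "down").to_numpy()
        assert (res.loc[up, "log2fc_internal"] > 0).all()
        assert (res.loc[down, "log2fc_internal"] < 0).all()

    def test_requires_two_replicates(self, default_maps, default_truth):
        with pytest.raises(ValueError):
            tad_foldchange_test(
                default_maps.condition(1)[:1], default_maps.condition(2),
                default_truth.tads,
            )


class TestSigmaCategories:
    def test_central_and_extreme_values(self):
        values = np.concatenate([np.zeros(50), [0.001], [10.0]])
        cats = sigma_categories(values)
        assert cats[50] == 4    # |z| < 0.5
        assert cats[51] == 7    # z > 2

    def test_matches_brute_force_binning(self, rng):
        values = rng.normal(0, 2, 500)
        cats = sigma_categories(values)
        z = (values - values.mean()) / values.std()
        edges = [-2, -1, -0.5, 0.5, 1, 2]
        expected = np.digitize(z, edges) + 1
        assert np.array_equal(cats, expected)
        assert set(np.unique(cats)) <= set(range(1, 8))

    def test_zero_sigma_raises(self):
        with pytest.raises(ValueError):
            sigma_categories([1.0, 1.0, 1.0])


class TestDegCategoryDistribution:
    def make_tests(self):
        tads = frame(("chr1", 0, 100), ("chr1", 100, 200), ("chr1", 200, 300))
        tads["sigma_category"] = [1, 4, 7]
        return tads

    def test_all_stable_genes(self):
        tads = self.make_tests()
        genes = [GeneRecord(f"g{i}", "chr1", 50 + 100 * i) for i in range(3)]
        table = deg_category_distribution(tads, genes)
        assert (table.loc["4", "prop_stable"]) == 1.0
        assert table.loc["total", "n_stable"] == 3

    def test_proportions_sum_to_one(self):
        tads = self.make_tests()
        genes = [
            GeneRecord("g1", "chr1", 50, de_status="up"),
            GeneRecord("g2", "chr1", 60, de_status="down"),
            GeneRecord("g3", "chr1", 150, de_status="stable"),
            GeneRecord("g4", "chr1", 250, de_status="up"),
        ]
        table = deg_category_distribution(tads, genes)
        sums = table[["prop_up", "prop_down", "prop_stable"]].sum(axis=1)
        occupied = table[["n_up", "n_down", "n_stable"]].sum(axis=1) > 0
        assert np.allclose(sums[occupied], 1.0, atol=1e-12)

    def test_gene_outside_tads_in_no_tad_bucket(self):
        tads = self.make_tests()
        genes = [GeneRecord("g1", "chr1", 10_000)]
        table = deg_category_distribution(tads, genes)
        assert table.loc["no_tad", "n_stable"] == 1
        assert table.loc["total", "n_stable"] == 0

    def test_boost_coupled_degs_enrich_extreme_categories(self):
        """Up-regulated genes concentrate in interaction-gaining TADs."""
        config = TruthConfig(seed=9, frac_boosted_tads=0.3, tad_boost=2.0)
        truth = generate_truth(config)
        sim = simulate_contact_maps(truth)
        res = tad_foldchange_test(sim.condition(1), sim.condition(2),
                                  truth.tads)
        res["sigma_category"] = sigma_categories(res["log2fc_internal"])
        # plant DE labels coupled to the TAD boost direction
        boost_of = truth.tads["boost"]
        genes = []
        for row in truth.genes.itertuples():
            tad = truth.tad_of_bin[row.bin]
            status = {"up": "up", "down": "down", "neutral": "stable"}[
                boost_of.iloc[tad]
            ]
            genes.append(GeneRecord(row.gene_id, row.chrom, int(row.tss),
                                    de_status=status))
        table = deg_category_distribution(res, genes)
        top = table.loc[["6", "7"]].sum()
        bottom = table.loc[["1", "2"]].sum()
        total = table.loc["total"]
        n_top = top[["n_up", "n_down", "n_stable"]].sum()
        n_bot = bottom[["n_up", "n_down", "n_stable"]].sum()
        assert top["n_up"] / n_top > total["prop_up"]
        assert bottom["n_down"] / n_bot > total["prop_down"]


class TestBoundaryStability:
    def test_identical_sets_fully_stable(self):
        tads = frame(("chr1", 0, 100), ("chr1", 100, 250))
        fraction, _ = boundary_stability(tads, tads, tolerance=10)
        assert fraction == 1.0

    def test_shift_within_tolerance_still_stable(self):
        tads1 = frame(("chr1", 0, 400_000), ("chr1", 400_000, 800_000))
        shifted = frame(("chr1", 160_000, 560_000), ("chr1", 560_000, 960_000))
        fraction, _ = boundary_stability(tads1, shifted, tolerance=200_000)
        assert fraction == 1.0

    def test_matches_exhaustive_scan(self, rng):
        def random_tads(seed_offset):
            starts = np.sort(rng.choice(np.arange(0, 10_000, 10), 20,
                                        replace=False))
            rows = [("chr1", int(s), int(e))
                    for s, e in zip(starts[:-1], starts[1:])]
            return frame(*rows)

        t1, t2 = random_tads(0), random_tads(1)
        fraction, table = boundary_stability(t1, t2, tolerance=25)
        b1 = np.unique(np.concatenate([t1["start"], t1["end"]]))
        b2 = np.unique(np.concatenate([t2["start"], t2["end"]]))
        expected = np.mean([min(abs(b - x) for x in b2) <= 25 for b in b1])
        assert fraction == pytest.approx(expected)
        assert len(table) == len(b1)

    def test_empty_set_raises(self):
        tads = frame(("chr1", 0, 100))
        with pytest.raises(ValueError):
            boundary_stability(tads, tads.iloc[0:0])


class TestAssignGenes:
    def test_tss_containment(self):
        tads = frame(("chr1", 0, 100), ("chr1", 100, 200), ("chr2", 0, 50))
        genes = [
            GeneRecord("g1", "chr1", 99),
            GeneRecord("g2", "chr1", 100),
            GeneRecord("g3", "chr2", 10),
            GeneRecord("g4", "chr3", 10),
        ]
        got = assign_genes_to_tads(genes, tads)
        assert got.tolist() == [0, 1, 2, -1]

    def test_tads_to_frame_round_trip(self):
        tads = tads_to_frame([GenomicInterval("chr1", 0, 100)])
        assert tads.iloc[0].tolist() == ["chr1", 0, 100]
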