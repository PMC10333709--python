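"""Generator contracts: reproducibility, truth completeness, distributions."""

import numpy as np
import pandas as pd
import pytest

from cellpool import (SimulationConfig, simulate_allele_counts,
                      simulate_cluster_counts, simulate_genotypes,
                      simulate_hashtag_run, simulate_study)
from cellpool.hashtag import log10p1

from conftest import make_cluster_params


class TestGenotypes:
    def test_zero_maf_is_all_reference(self):
        g = simulate_genotypes(3, 4, 0.0, 0.0, seed=1)
        assert g.shape == (3, 4)
        assert (g.to_numpy() == 0).all()

    def test_dosages_in_domain(self):
        g = simulate_genotypes(1, 10, 0.05, 0.5, seed=7)
        assert set(np.unique(g.to_numpy())) <= {0, 1, 2}

    def test_mean_dosage_tracks_allele_frequency(self):
        # At f = 0.5 each dosage is Binomial(2, 0.5) with mean 1, so the
        # empirical mean over 50 donors stays within 3 binomial SEs.
        g = simulate_genotypes(50, 1, 0.5, 0.5, seed=11)
        se = np.sqrt(2 * 0.5 * 0.5 / 50)
        assert abs(g.to_numpy().mean() - 1.0) <= 3 * se

    @pytest.mark.parametrize("kwargs", [
        dict(n_donors=0, n_snps=5, maf_low=0.1, maf_high=0.5),
        dict(n_donors=5, n_snps=0, maf_low=0.1, maf_high=0.5),
        dict(n_donors=5, n_snps=5, maf_low=0.4, maf_high=0.1),
        dict(n_donors=5, n_snps=5, maf_low=0.1, maf_high=0.7),
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            simulate_genotypes(seed=1, **kwargs)

    def test_same_seed_bit_exact(self):
        a = simulate_genotypes(10, 20, 0.1, 0.5, seed=3)
        b = simulate_genotypes(10, 20, 0.1, 0.5, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestHashtagRun:
    def test_no_doublets_when_rate_zero(self):
        cfg = SimulationConfig(donors_per_run=3, cells_per_donor=50,
                               doublet_rate=0.0, seed=2)
        _, truth = simulate_hashtag_run(cfg, "run1")
        assert not truth.cell_to_donor["is_doublet"].any()
        assert (truth.cell_to_donor["donor_b"] == "").all()

    def test_component_means_recovered_from_truth(self):
        # Sample means of own-hashtag vs other-hashtag log-counts should sit
        # within 3 SEs of the generating component means.
        cfg = SimulationConfig(donors_per_run=2, cells_per_donor=2000,
                               doublet_rate=0.0, mu_lo=1.0, mu_hi=2.5,
                               sigma_lo=0.2, sigma_hi=0.2, seed=3)
        counts, truth = simulate_hashtag_run(cfg, "run1")
        labels = truth.cell_to_donor.set_index("cell_id")["donor_a"]
        x = log10p1(counts)
        own = np.concatenate([
            x[labels.to_numpy() == h, j]
            for j, h in enumerate(counts.columns)])
        other = np.concatenate([
            x[labels.to_numpy() != h, j]
            for j, h in enumerate(counts.columns)])
        # rounding to integer counts perturbs the log-scale draws slightly;
        # allow the discretization bias on top of the 3-SE band
        assert abs(own.mean() - 2.5) < 3 * 0.2 / np.sqrt(len(own)) + 0.01
        assert abs(other.mean() - 1.0) < 3 * 0.2 / np.sqrt(len(other)) + 0.02

    def test_matrix_dimensions_and_truth_cover_all_cells(self):
        cfg = SimulationConfig(donors_per_run=4, cells_per_donor=25, seed=5)
        counts, truth = simulate_hashtag_run(cfg, "runX")
        assert counts.shape == (100, 4)
        assert set(truth.cell_to_donor["cell_id"]) == set(counts.index)

    def test_empty_run(self):
        cfg = SimulationConfig(donors_per_run=3, cells_per_donor=0, seed=5)
        counts, truth = simulate_hashtag_run(cfg, "run1")
        assert counts.shape == (0, 3)
        assert len(truth.cell_to_donor) == 0

    def test_default_pool_size_is_fifteen(self):
        assert SimulationConfig().donors_per_run == 15

    def test_doublets_get_two_distinct_donors(self):
        cfg = SimulationConfig(donors_per_run=5, cells_per_donor=200,
                               doublet_rate=0.3, seed=6)
        _, truth = simulate_hashtag_run(cfg, "run1")
        dbl = truth.cell_to_donor.query("is_doublet")
        assert len(dbl) > 0
        assert (dbl["donor_a"] != dbl["donor_b"]).all()


class TestAlleleCounts:
    def test_zero_depth_mean_gives_no_rows(self, small_study):
        truth = small_study["truth"]
        out = simulate_allele_counts(truth, small_study["genotypes"],
                                     depth_mean=0.0, error_rate=0.01, seed=1)
        assert len(out) == 0

    def test_zero_error_reference_dosage_gives_no_alt(self):
        cfg = SimulationConfig(donors_per_run=2, cells_per_donor=30,
                               doublet_rate=0.0, seed=4)
        _, truth = simulate_hashtag_run(cfg, "run1")
        geno = simulate_genotypes(2, 10, 0.0, 0.0, seed=4,
                                  donor_ids=["donor01", "donor02"])
        out = simulate_allele_counts(truth, geno, depth_mean=5.0,
                                     error_rate=0.0, seed=4)
        assert (out["alt_count"] == 0).all()

    def test_het_alt_fraction_near_half(self):
        # dosage 1 at high depth: alt fraction within 3 binomial SEs of 0.5
        cfg = SimulationConfig(donors_per_run=1, cells_per_donor=1,
                               doublet_rate=0.0, seed=9)
        _, truth = simulate_hashtag_run(cfg, "run1")
        geno = pd.DataFrame([[1]], index=pd.Index(["donor01"]),
                            columns=pd.Index(["snp0001"]))
        out = simulate_allele_counts(truth, geno, depth_mean=200.0,
                                     error_rate=0.0, seed=9)
        frac = out["alt_count"].sum() / (out["alt_count"] + out["ref_count"]).sum()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 200)

    def test_error_rate_half_rejected(self, small_study):
        with pytest.raises(ValueError):
            simulate_allele_counts(small_study["truth"],
                                   small_study["genotypes"],
                                   depth_mean=1.0, error_rate=0.5, seed=1)


class TestClusterCounts:
    def test_no_variation_sources_share_probability(self, paired_design):
        params = make_cluster_params(beta1=0.0, sigma_u=0.0, sigma_e=0.0,
                                     beta0=0.0)
        tab, _, eff = simulate_cluster_counts(paired_design, params,
                                              total_sampler=100000, seed=5)
        # logistic(0) = 0.5 for every sample; frequencies concentrate there
        frac = tab["count"] / tab["total"]
        assert (eff[["u_donor", "e_sample"]].to_numpy() == 0).all()
        assert abs(frac.mean() - 0.5) < 0.005

    def test_challenge_effect_shifts_after_samples(self, paired_design):
        params = make_cluster_params(beta1=1.5, sigma_u=0.0, sigma_e=0.0)
        tab, _, _ = simulate_cluster_counts(paired_design, params,
                                            total_sampler=5000, seed=6)
        before = tab.loc[tab.timepoint == "before", "count"].mean()
        after = tab.loc[tab.timepoint == "after", "count"].mean()
        assert after > before * 2

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            simulate_cluster_counts(pd.DataFrame(columns=["donor_id", "group",
                                                          "timepoint"]),
                                    make_cluster_params(0.0), 100, seed=1)

    def test_duplicate_timepoint_rejected(self):
        design = pd.DataFrame([
            {"donor_id": "d1", "group": "g", "timepoint": "before"},
            {"donor_id": "d1", "group": "g", "timepoint": "before"},
        ])
        with pytest.raises(ValueError):
            simulate_cluster_counts(design, make_cluster_params(0.0), 100,
                                    seed=1)


class TestStudyReproducibility:
    def test_same_config_and_seed_bit_exact(self):
        cfg = SimulationConfig(n_runs=2, donors_per_run=3,
                               cells_per_donor=40, n_snps=20, seed=17)
        a, b = simulate_study(cfg), simulate_study(cfg)
        for rid in a["hashtag_counts"]:
            pd.testing.assert_frame_equal(a["hashtag_counts"][rid],
                                          b["hashtag_counts"][rid])
            pd.testing.assert_frame_equal(a["allele_counts"][rid],
                                          b["allele_counts"][rid])
        pd.testing.assert_frame_equal(a["genotypes"], b["genotypes"])
        pd.testing.assert_frame_equal(a["truth"].cell_to_donor,
                                      b["truth"].cell_to_donor)

    def test_truth_labels_every_cell(self, small_study):
        cells = set()
        for counts in small_study["hashtag_counts"].values():
            cells |= set(counts.index)
        assert set(small_study["truth"].cell_to_donor["cell_id"]) == cells
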