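"""Genotype calling, concordance and genotype-based donor assignment.

The genotype caller and the per-cell assignment are checked against a
brute-force evaluation of the three-state binomial likelihood
(q_0 = eps, q_1 = 0.5, q_2 = 1 - eps).
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from cellpool import (SimulationConfig, aggregate_counts_by_sample,
                      assign_by_genotype, call_genotypes, concordance_table,
                      genotype_concordance, pool_allele_counts,
                      pool_donor_genotypes, select_informative_snps,
                      simulate_allele_counts, simulate_study)
from cellpool.genotype import MISSING, GenotypeLinkageWarning


def brute_force_call(ref, alt, eps):
    """Independent oracle: enumerate the three dosage likelihoods."""
    qs = [eps, 0.5, 1.0 - eps]
    lls = [binom.logpmf(alt, ref + alt, q) for q in qs]
    best = max(lls)
    # ties toward het
    return 1 if lls[1] == best else int(np.argmax(lls))


def sample_counts(rows):
    return pd.DataFrame(rows, columns=["sample_id", "snp_id", "ref_count",
                                       "alt_count"])


class TestSNPSelection:
    def test_monomorphic_excluded(self):
        pooled = pd.DataFrame({"snp_id": ["s1"], "pooled_ref": [100],
                               "pooled_alt": [0]})
        assert len(select_informative_snps(pooled)) == 0

    def test_depth_boundary(self):
        pooled = pd.DataFrame({"snp_id": ["s1", "s2"],
                               "pooled_ref": [30, 31],
                               "pooled_alt": [19, 19]})
        out = select_informative_snps(pooled, min_depth=50)
        assert list(out["snp_id"]) == ["s2"]

    def test_polymorphic_snps_mostly_retained(self, small_study):
        counts = pd.concat(small_study["allele_counts"].values(),
                           ignore_index=True)
        panel = select_informative_snps(pool_allele_counts(counts))
        geno = small_study["genotypes"]
        poly = geno.columns[(geno.nunique() > 1) | (geno.iloc[0] == 1)]
        retained = set(panel["snp_id"])
        assert len(retained & set(poly)) / len(poly) >= 0.90


class TestAggregation:
    def test_single_cell_identity(self):
        counts = pd.DataFrame({"cell_id": ["c1"], "snp_id": ["s1"],
                               "ref_count": [3], "alt_count": [1]})
        agg = aggregate_counts_by_sample(counts, {"c1": "A"})
        assert agg.iloc[0][["ref_count", "alt_count"]].tolist() == [3, 1]

    def test_addition_and_permutation(self):
        counts = pd.DataFrame({
            "cell_id": ["c1", "c2"], "snp_id": ["s1", "s1"],
            "ref_count": [3, 2], "alt_count": [1, 2]})
        agg = aggregate_counts_by_sample(counts, {"c1": "A", "c2": "A"})
        assert agg.iloc[0][["ref_count", "alt_count"]].tolist() == [5, 3]
        agg_rev = aggregate_counts_by_sample(counts.iloc[::-1],
                                             {"c1": "A", "c2": "A"})
        pd.testing.assert_frame_equal(agg, agg_rev)

    def test_unmapped_cells_ignored_and_totals_conserved(self):
        counts = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3"], "snp_id": ["s1"] * 3,
            "ref_count": [1, 2, 4], "alt_count": [0, 1, 1]})
        agg = aggregate_counts_by_sample(counts, {"c1": "A", "c2": "B"})
        assert agg["ref_count"].sum() == 3 and agg["alt_count"].sum() == 1


class TestGenotypeCaller:
    def test_matches_brute_force_oracle(self, rng):
        rows, expected = [], []
        for i in range(300):
            depth = int(rng.integers(5, 31))
            alt = int(rng.integers(0, depth + 1))
            rows.append(("s", f"snp{i}", depth - alt, alt))
            expected.append(brute_force_call(depth - alt, alt, 0.01))
        geno = call_genotypes(sample_counts(rows), error_rate=0.01,
                              min_call_depth=5)
        got = geno.loc["s", [f"snp{i}" for i in range(300)]].tolist()
        assert got == expected

    def test_textbook_cases(self):
        geno = call_genotypes(sample_counts([
            ("s", "a", 20, 0), ("s", "b", 10, 10), ("s", "c", 0, 20),
            ("s", "d", 0, 0)]), error_rate=0.01)
        assert geno.loc["s", "a"] == 0
        assert geno.loc["s", "b"] == 1
        assert geno.loc["s", "c"] == 2
        assert geno.loc["s", "d"] == MISSING  # below min_call_depth

    def test_invalid_error_rate(self):
        with pytest.raises(ValueError):
            call_genotypes(sample_counts([("s", "a", 1, 1)]), error_rate=0.6)


class TestConcordance:
    def test_identical_vectors(self):
        a = pd.Series([0, 1, 2, 1], index=list("wxyz"))
        c, n = genotype_concordance(a, a)
        assert c == 1.0 and n == 4

    def test_no_shared_snps_undefined(self):
        a = pd.Series([MISSING, 1], index=["x", "y"])
        b = pd.Series([1, MISSING], index=["x", "y"])
        c, n = genotype_concordance(a, b)
        assert np.isnan(c) and n == 0

    def test_symmetry(self, rng):
        a = pd.Series(rng.integers(-1, 3, 30))
        b = pd.Series(rng.integers(-1, 3, 30))
        assert genotype_concordance(a, b) == genotype_concordance(b, a)

    def test_same_donor_pairs_separate_completely(self, small_study):
        # two runs of the same donors: every same-donor concordance must
        # exceed every different-donor concordance
        counts = pd.concat(small_study["allele_counts"].values(),
                           ignore_index=True)
        truth = small_study["truth"].cell_to_donor
        singles = truth[~truth["is_doublet"]]
        amap = pd.Series(
            (singles["run_id"] + "/" + singles["donor_a"]).to_numpy(),
            index=singles["cell_id"].to_numpy())
        agg = aggregate_counts_by_sample(counts, amap)
        geno = call_genotypes(agg)
        tab = concordance_table(
            geno, same_donor={s: s.split("/")[1] for s in geno.index})
        same = tab.loc[tab["same_donor_expected"], "concordance"]
        diff = tab.loc[~tab["same_donor_expected"], "concordance"]
        assert same.min() > diff.max()


class TestPooling:
    def test_single_run_identity(self):
        counts = sample_counts([("run1/A", "s1", 10, 0),
                                ("run1/A", "s2", 5, 5)])
        sg = call_genotypes(counts)
        dg = pool_donor_genotypes(counts, {"run1/A": "A"})
        assert (dg.loc["A"] == sg.loc["run1/A"]).all()

    def test_pooled_missingness_shrinks(self):
        counts = sample_counts([
            ("run1/A", "s1", 3, 0), ("run1/A", "s2", 10, 0),
            ("run2/A", "s1", 3, 0), ("run2/A", "s2", 0, 0)])
        sg = call_genotypes(counts)
        assert sg.loc["run1/A", "s1"] == MISSING
        dg = pool_donor_genotypes(counts, {"run1/A": "A", "run2/A": "A"})
        assert dg.loc["A", "s1"] == 0  # depth 6 after pooling

    def test_bad_link_warns(self, small_study):
        counts = pd.concat(small_study["allele_counts"].values(),
                           ignore_index=True)
        truth = small_study["truth"].cell_to_donor
        singles = truth[~truth["is_doublet"]]
        amap = pd.Series(
            (singles["run_id"] + "/" + singles["donor_a"]).to_numpy(),
            index=singles["cell_id"].to_numpy())
        agg = aggregate_counts_by_sample(counts, amap)
        sg = call_genotypes(agg)
        # deliberately link two different donors as if they were one
        links = {s: s.split("/")[1] for s in sg.index}
        wrong = [s for s in sg.index if s.startswith("run2/")][:2]
        links[wrong[0]] = links[wrong[1]].replace("run2/", "")
        links[wrong[0]] = links[wrong[1]]
        with pytest.warns(GenotypeLinkageWarning):
            pool_donor_genotypes(agg, links, validate_with=sg)

    def test_pooled_accuracy_against_truth(self, small_study):
        counts = pd.concat(small_study["allele_counts"].values(),
                           ignore_index=True)
        truth = small_study["truth"].cell_to_donor
        singles = truth[~truth["is_doublet"]]
        amap = pd.Series(
            (singles["run_id"] + "/" + singles["donor_a"]).to_numpy(),
            index=singles["cell_id"].to_numpy())
        agg = aggregate_counts_by_sample(counts, amap)
        links = {s: s.split("/")[1] for s in agg["sample_id"].unique()}
        dg = pool_donor_genotypes(agg, links)
        tg = small_study["genotypes"].loc[dg.index, dg.columns].to_numpy()
        called = dg.to_numpy() != MISSING
        assert (dg.to_numpy() == tg)[called].mean() >= 0.99


class TestAssignByGenotype:
    def test_alt_only_cell_matches_hom_alt_donor(self):
        geno = pd.DataFrame(
            [[2] * 5, [0] * 5, [0] * 5],
            index=pd.Index(["A", "B", "C"], name="donor_id"),
            columns=[f"s{i}" for i in range(5)])
        counts = pd.DataFrame({
            "cell_id": ["c"] * 5, "snp_id": [f"s{i}" for i in range(5)],
            "ref_count": [0] * 5, "alt_count": [4] * 5})
        calls = assign_by_genotype(counts, geno, error_rate=0.01)
        assert calls.loc[0, "donor_call"] == "A"
        # winning log-likelihood matches the brute-force binomial product
        # (coefficients omitted in both): 5 SNPs x log(0.99^4)
        assert np.isclose(calls.loc[0, "log_likelihood"],
                          5 * 4 * np.log(0.99), atol=1e-9)

    def test_matches_brute_force_on_random_cases(self, rng):
        n_donors, n_snps = 4, 8
        geno_arr = rng.integers(0, 3, size=(n_donors, n_snps))
        geno = pd.DataFrame(geno_arr,
                            index=pd.Index([f"d{i}" for i in range(n_donors)],
                                           name="donor_id"),
                            columns=[f"s{j}" for j in range(n_snps)])
        eps = 0.01
        qs = np.array([eps, 0.5, 1 - eps])
        rows = []
        for c in range(50):
            for j in range(n_snps):
                depth = int(rng.integers(0, 7))
                if depth == 0:
                    continue
                alt = int(rng.integers(0, depth + 1))
                rows.append((f"c{c:02d}", f"s{j}", depth - alt, alt))
        counts = pd.DataFrame(rows, columns=["cell_id", "snp_id",
                                             "ref_count", "alt_count"])
        calls = assign_by_genotype(counts, geno, error_rate=eps,
                                   min_margin=0.0, min_informative=1)
        for cid, sub in counts.groupby("cell_id"):
            lls = []
            for d in range(n_donors):
                ll = 0.0
                for _, r in sub.iterrows():
                    g = geno_arr[d, int(r["snp_id"][1:])]
                    dep = r["ref_count"] + r["alt_count"]
                    ll += binom.logpmf(r["alt_count"], dep, qs[g])
                lls.append(ll)
            expect = f"d{int(np.argmax(lls))}"
            got = calls.set_index("cell_id").loc[cid, "best_donor"]
            assert got == expect, cid

    def test_zero_coverage_null(self):
        geno = pd.DataFrame([[0, 1], [2, 1]],
                            index=pd.Index(["A", "B"], name="donor_id"),
                            columns=["s0", "s1"])
        counts = pd.DataFrame({"cell_id": ["c"], "snp_id": ["s0"],
                               "ref_count": [0], "alt_count": [0]})
        calls = assign_by_genotype(counts, geno)
        assert calls.loc[0, "donor_call"] is None

    def test_empty_donor_set_rejected(self):
        counts = pd.DataFrame({"cell_id": ["c"], "snp_id": ["s0"],
                               "ref_count": [1], "alt_count": [0]})
        with pytest.raises(ValueError):
            assign_by_genotype(counts, pd.DataFrame())

    def test_snp_order_invariance(self, small_study):
        counts = small_study["allele_counts"]["run1"]
        geno = small_study["genotypes"]
        a = assign_by_genotype(counts, geno)
        b = assign_by_genotype(counts.sample(frac=1.0, random_state=0),
                               geno.iloc[:, ::-1])
        pd.testing.assert_series_equal(
            a.set_index("cell_id")["donor_call"].sort_index(),
            b.set_index("cell_id")["donor_call"].sort_index())

    def test_uninformative_locus_invariance(self, small_study):
        counts = small_study["allele_counts"]["run1"].copy()
        geno = small_study["genotypes"]
        a = assign_by_genotype(counts, geno)
        # add a SNP where every donor is het: rankings cannot change
        geno2 = geno.copy()
        geno2["snp_flat"] = 1
        extra = pd.DataFrame({
            "cell_id": counts["cell_id"].unique(),
            "snp_id": "snp_flat", "ref_count": 2, "alt_count": 2})
        b = assign_by_genotype(pd.concat([counts, extra], ignore_index=True),
                               geno2)
        pd.testing.assert_series_equal(
            a.set_index("cell_id")["best_donor"].sort_index(),
            b.set_index("cell_id")["best_donor"].sort_index())

    def test_synthetic_accuracy_and_call_rate(self, small_study):
        counts = pd.concat(small_study["allele_counts"].values(),
                           ignore_index=True)
        truth = small_study["truth"].cell_to_donor
        calls = assign_by_genotype(counts, small_study["genotypes"])
        merged = calls.merge(truth, on="cell_id")
        singlets = merged[~merged["is_doublet"]]
        called = singlets[singlets["donor_call"].notna()]
        assert (called["donor_call"] == called["donor_a"]).mean() >= 0.99
        assert merged["donor_call"].notna().mean() >= 0.90

    def test_accuracy_nondecreasing_in_depth(self):
        accs = []
        for depth in (2.0, 10.0, 50.0):
            cfg = SimulationConfig(n_runs=1, donors_per_run=5,
                                   cells_per_donor=80, n_snps=60,
                                   depth_mean=depth, doublet_rate=0.0,
                                   seed=31)
            study = simulate_study(cfg)
            counts = study["allele_counts"]["run1"]
            calls = assign_by_genotype(counts, study["genotypes"],
                                       min_margin=0.0, min_informative=1)
            merged = calls.merge(study["truth"].cell_to_donor, on="cell_id")
            accs.append((merged["best_donor"] == merged["donor_a"]).mean())
        assert accs[0] <= accs[1] + 0.01 and accs[1] <= accs[2] + 0.01
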