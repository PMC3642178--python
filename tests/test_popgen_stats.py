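"""Diversity, disequilibrium and differentiation estimators against
independent oracles and analytic limits."""

import numpy as np
import pytest
from scipy.stats import kstest

from oxbowflow import popgen_stats as ps
from oxbowflow.study_io import GenotypeTable, SiteMetadata

from conftest import random_table


def table_from_rows(rows, sites, loci=("A",)):
    arr = np.asarray(rows, dtype=np.int32).reshape(len(rows), len(loci), 2)
    return GenotypeTable(
        tuple(f"i{k}" for k in range(len(rows))), tuple(sites), loci, arr
    )


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive, loop-based implementations)
# ---------------------------------------------------------------------------


def oracle_wc_theta(pops):
    """Two-population Weir-Cockerham theta, direct transcription of the
    variance-component formulas with explicit loops (single locus)."""
    r = len(pops)
    ns = [len(p) for p in pops]
    alleles = sorted({a for p in pops for g in p for a in g})
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for u in alleles:
        p_i = [sum(g.count(u) for g in p) / (2 * n) for p, n in zip(pops, ns)]
        h_i = [
            sum(1 for g in p if g[0] != g[1] and u in g) / n
            for p, n in zip(pops, ns)
        ]
        pbar = sum(n * pi for n, pi in zip(ns, p_i)) / (r * nbar)
        s2 = sum(n * (pi - pbar) ** 2 for n, pi in zip(ns, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * hi for n, hi in zip(ns, h_i)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        A += a
        B += b
        C += hbar / 2
    return A / (A + B + C)


def oracle_nei_chesser(pops):
    """Unbiased (H_S, H_T) for k pops at one locus."""
    k = len(pops)
    ns = [len(p) for p in pops]
    ntilde = k / sum(1.0 / n for n in ns)
    alleles = sorted({a for p in pops for g in p for a in g})
    P = [[sum(g.count(u) for g in p) / (2 * n) for u in alleles] for p, n in zip(pops, ns)]
    ho = sum(sum(1 for g in p if g[0] != g[1]) / n for p, n in zip(pops, ns)) / k
    hs_raw = 1 - sum(sum(x * x for x in row) for row in P) / k
    hs = ntilde / (ntilde - 1) * (hs_raw - ho / (2 * ntilde))
    pbar = [sum(P[i][j] for i in range(k)) / k for j in range(len(alleles))]
    ht = 1 - sum(x * x for x in pbar) + hs / (k * ntilde) - ho / (2 * k * ntilde)
    return hs, ht


def pops_from_table(table, sites, locus=0):
    out = []
    for s in sites:
        block = table.alleles[table.site_mask(s)][:, locus, :]
        out.append([tuple(g) for g in block if g[0] != 0])
    return out


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


class TestDiversity:
    def test_nei_diversity_formula(self):
        assert ps.nei_unbiased_diversity({1: 1.0}, 20) == 0.0
        assert ps.nei_unbiased_diversity({1: 0.5, 2: 0.5}, 10) == pytest.approx(
            0.5556, abs=1e-4
        )
        with pytest.raises(ps.UndefinedStatistic):
            ps.nei_unbiased_diversity({1: 1.0}, 1)

    def test_allele_frequencies_match_direct_tally(self):
        t = random_table(5, n_ind=30, n_loci=4, n_sites=1, missing_rate=0.2)
        site = t.site_ids[0]
        freqs = ps.allele_frequencies(t, site)
        for l, locus in enumerate(t.loci):
            genes = [
                a
                for row in t.alleles[t.site_mask(site)][:, l, :]
                if row[0] != 0
                for a in row
            ]
            for allele, f in freqs[locus].items():
                assert f == pytest.approx(genes.count(allele) / len(genes))
            assert sum(freqs[locus].values()) == pytest.approx(1.0)

    def test_observed_heterozygosity_limits(self):
        t = table_from_rows([[10, 10]] * 4, ["s"] * 4)
        assert ps.observed_heterozygosity(t, "s")[1] == 0.0
        t = table_from_rows([[10, 12]] * 4, ["s"] * 4)
        assert ps.observed_heterozygosity(t, "s")[1] == 1.0

    def test_fis_is_one_without_heterozygotes(self):
        t = table_from_rows([[10, 10]] * 5 + [[12, 12]] * 5, ["s"] * 10)
        assert ps.fis_weir_cockerham(t, "s")[1] == pytest.approx(1.0)

    def test_fis_near_zero_under_hardy_weinberg(self):
        # genotypes drawn as independent gene copies: E[f] = 0; n chosen
        # large enough that sampling noise (sd ~ 1/sqrt(n)) sits well
        # inside the band
        rng = np.random.default_rng(0)
        genes = rng.choice([10, 12], p=[0.6, 0.4], size=(2000, 3, 2))
        t = GenotypeTable(
            tuple(f"i{k}" for k in range(2000)), ("s",) * 2000, ("A", "B", "C"),
            genes.astype(np.int32),
        )
        assert abs(ps.fis_weir_cockerham(t, "s")[1]) < 0.05

    def test_fis_undefined_when_all_monomorphic(self):
        t = table_from_rows([[10, 10]] * 5, ["s"] * 5)
        with pytest.raises(ps.UndefinedStatistic):
            ps.fis_weir_cockerham(t, "s")


class TestRarefaction:
    def test_full_depth_returns_observed_count(self):
        assert ps.rarefied_richness({1: 5, 2: 5}, 10) == pytest.approx(2.0)

    def test_fixed_allele_contributes_one(self):
        for g in (1, 3, 9):
            assert ps.rarefied_richness({7: 10}, g) == pytest.approx(1.0)

    def test_against_monte_carlo_subsampling(self):
        counts = {1: 7, 2: 5, 3: 2, 4: 1}
        rng = np.random.default_rng(1)
        genes = np.repeat(list(counts), list(counts.values()))
        draws = [
            len(np.unique(rng.choice(genes, 6, replace=False)))
            for _ in range(100_000)
        ]
        assert ps.rarefied_richness(counts, 6) == pytest.approx(
            np.mean(draws), abs=0.01
        )

    def test_monotone_in_depth(self):
        counts = {1: 9, 2: 6, 3: 3, 4: 2}
        vals = [ps.rarefied_richness(counts, g) for g in range(1, 21)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_depth_beyond_copies_is_an_error(self):
        with pytest.raises(ps.UndefinedStatistic):
            ps.rarefied_richness({1: 4}, 5)


# ---------------------------------------------------------------------------
# HWE / LD / Bonferroni
# ---------------------------------------------------------------------------


class TestHWE:
    def test_monomorphic_gives_p_one(self):
        t = table_from_rows([[10, 10]] * 5, ["s"] * 5)
        assert ps.hwe_exact_test(t, "s", "A") == 1.0

    def test_monte_carlo_agrees_with_two_allele_enumeration(self):
        rows = [[10, 10]] * 3 + [[10, 12]] * 4 + [[12, 12]] * 3
        t = table_from_rows(rows, ["s"] * 10)
        exact = ps.hwe_exact_test(t, "s", "A")
        mc = ps.hwe_exact_test(t, "s", "A", mc_reps=20_000, seed=1, force_mc=True)
        se = np.sqrt(exact * (1 - exact) / 20_000)
        assert abs(mc - exact) < 3 * se + 1e-3

    def test_wahlund_mixture_shows_heterozygote_deficit(self):
        rows = [[10, 10]] * 20 + [[12, 12]] * 20 + [[10, 12]] * 2
        t = table_from_rows(rows, ["s"] * 42)
        assert ps.hwe_exact_test(t, "s", "A") < 0.01


class TestLD:
    def test_duplicated_locus_is_detected(self):
        rng = np.random.default_rng(2)
        g = rng.integers(10, 14, size=(30, 1, 2)).astype(np.int32)
        arr = np.concatenate([g, g], axis=1)
        t = GenotypeTable(
            tuple(f"i{k}" for k in range(30)), ("s",) * 30, ("A", "B"), arr
        )
        assert ps.ld_permutation_test(t, "s", ("A", "B"), n_perm=999, seed=0) <= 0.01

    def test_refuses_too_few_permutations(self):
        t = random_table(3, n_ind=10, n_loci=2, n_sites=1, missing_rate=0)
        with pytest.raises(ValueError):
            ps.ld_permutation_test(t, t.site_ids[0], ("L0", "L1"), n_perm=50)

    def test_null_p_values_are_uniform(self):
        # dense 3x3 genotype tables (two alleles, n = 60) keep ties in the
        # G statistic rare, so the permutation p-value is near-uniform
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(200):
            arr = rng.choice([10, 12], size=(60, 2, 2)).astype(np.int32)
            t = GenotypeTable(
                tuple(f"i{k}" for k in range(60)), ("s",) * 60, ("A", "B"), arr
            )
            pvals.append(
                ps.ld_permutation_test(t, "s", ("A", "B"), n_perm=199, seed=rep)
            )
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_single_test_threshold_is_alpha(self):
        r = ps.bonferroni([0.03], 0.05)
        assert r.threshold == 0.05 and r.flags.tolist() == [True]

    def test_boundary_is_inclusive(self):
        r = ps.bonferroni([0.05 / 4, 0.2, 0.3, 0.4], 0.05)
        assert r.flags.tolist() == [True, False, False, False]

    def test_family_of_143_tests(self):
        r = ps.bonferroni([0.5] * 143, 0.05)
        assert r.threshold == pytest.approx(0.0003497, abs=1e-7)

    def test_empty_family_is_an_error(self):
        with pytest.raises(ValueError):
            ps.bonferroni([], 0.05)


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------


class TestDifferentiation:
    def fixed_diff_table(self):
        return table_from_rows(
            [[10, 10]] * 6 + [[12, 12]] * 6, ["a"] * 6 + ["b"] * 6
        )

    def test_fixed_differences_reach_one(self):
        t = self.fixed_diff_table()
        assert ps.pairwise_fst(t, "a", "b")[1] == pytest.approx(1.0)
        assert ps.gst_hedrick(t, "a", "b")[1] == pytest.approx(1.0)
        assert ps.d_est_jost(t, "a", "b")[1] == pytest.approx(1.0)

    def test_random_split_of_one_pool_is_near_zero(self):
        rng = np.random.default_rng(4)
        arr = rng.integers(10, 18, size=(60, 5, 2)).astype(np.int32)
        t = GenotypeTable(
            tuple(f"i{k}" for k in range(60)),
            tuple(["a"] * 30 + ["b"] * 30),
            tuple("ABCDE"),
            arr,
        )
        assert abs(ps.pairwise_fst(t, "a", "b")[1]) < 0.02
        assert abs(ps.d_est_jost(t, "a", "b")[1]) < 0.02

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_theta_matches_independent_oracle(self, seed):
        t = random_table(seed, n_ind=10, n_loci=1, n_sites=2, missing_rate=0.0)
        sites = t.site_ids
        if min(t.site_size(s) for s in sites) < 2:
            pytest.skip("degenerate random split")
        pops = pops_from_table(t, sites)
        expect = oracle_wc_theta(pops)
        assert ps.pairwise_fst(t, sites[0], sites[1])[1] == pytest.approx(
            expect, rel=1e-9, abs=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 5])
    def test_gst_and_dest_match_independent_formulas(self, seed):
        t = random_table(seed, n_ind=14, n_loci=1, n_sites=2, missing_rate=0.0)
        sites = t.site_ids
        if min(t.site_size(s) for s in sites) < 2:
            pytest.skip("degenerate random split")
        hs, ht = oracle_nei_chesser(pops_from_table(t, sites))
        gst = (ht - hs) / ht
        gmax = (2 - 1) * (1 - hs) / (2 - 1 + hs)
        d = (ht - hs) / (1 - hs) * 2
        assert ps.gst_hedrick(t, sites[0], sites[1])[1] == pytest.approx(
            gst / gmax, rel=1e-9
        )
        per_locus, _, d_mean = ps.d_est_jost(t, sites[0], sites[1])
        assert per_locus[0] == pytest.approx(d, rel=1e-9)

    def test_invariance_to_relabeling_and_site_order(self):
        t = random_table(9, n_ind=16, n_loci=3, n_sites=2, missing_rate=0.1)
        a, b = t.site_ids
        d1 = ps.d_est_jost(t, a, b)[1]
        g1 = ps.gst_hedrick(t, a, b)[1]
        # swap site order
        assert ps.d_est_jost(t, b, a)[1] == pytest.approx(d1, rel=1e-12)
        assert ps.gst_hedrick(t, b, a)[1] == pytest.approx(g1, rel=1e-12)
        # relabel alleles by an order-preserving shift
        shifted = GenotypeTable(
            t.individuals,
            t.site_of,
            t.loci,
            np.where(t.alleles > 0, t.alleles + 3, 0),
        )
        assert ps.d_est_jost(shifted, a, b)[1] == pytest.approx(d1, rel=1e-12)
        assert ps.gst_hedrick(shifted, a, b)[1] == pytest.approx(g1, rel=1e-12)

    def test_identical_duplicated_individual_is_undefined(self):
        t = table_from_rows([[10, 10]] * 4, ["a", "a", "b", "b"])
        with pytest.raises(ps.UndefinedStatistic):
            ps.pairwise_fst(t, "a", "b")


class TestPoolingCheck:
    def _meta(self, members):
        return SiteMetadata("parent", "control", "north", "west", "west",
                            members=tuple(members))

    def test_panmictic_locations_recommend_pooling(self):
        rng = np.random.default_rng(7)
        arr = rng.integers(10, 16, size=(40, 4, 2)).astype(np.int32)
        t = GenotypeTable(
            tuple(f"i{k}" for k in range(40)),
            tuple(["parent"] * 20 + ["loc_b"] * 20),
            tuple("ABCD"),
            arr,
        )
        check = ps.amova_pooling_check(t, self._meta(["loc_b"]), n_perm=199, seed=0)
        assert check.p_value > 0.05 and check.pooling_recommended

    def test_distinct_pools_are_detected(self):
        rng = np.random.default_rng(8)
        a = rng.integers(10, 13, size=(20, 4, 2))
        b = rng.integers(14, 17, size=(20, 4, 2))
        t = GenotypeTable(
            tuple(f"i{k}" for k in range(40)),
            tuple(["parent"] * 20 + ["loc_b"] * 20),
            tuple("ABCD"),
            np.concatenate([a, b]).astype(np.int32),
        )
        check = ps.amova_pooling_check(t, self._meta(["loc_b"]), n_perm=199, seed=0)
        assert check.p_value <= 0.05 and not check.pooling_recommended

    def test_single_location_is_an_error(self):
        t = random_table(1, n_ind=10, n_loci=2, n_sites=1)
        meta = SiteMetadata(t.site_ids[0], "control", "north", "west", "west")
        with pytest.raises(ps.UndefinedStatistic):
            ps.amova_pooling_check(t, meta)


def test_diversity_summary_respects_invariants(default_study):
    dataset, _ = default_study
    df = ps.diversity_summary(dataset.genotypes)
    assert ((df["H_E"] >= 0) & (df["H_E"] <= 1)).all()
    assert ((df["H_O"] >= 0) & (df["H_O"] <= 1)).all()
    assert (df["A_R_star"] <= df["A_R"] + 1e-9).all()
    assert (df["A_R"] <= df["A_N"] + 1e-9).all()
    assert ((df["F_IS"] >= -1) & (df["F_IS"] <= 1)).all()
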