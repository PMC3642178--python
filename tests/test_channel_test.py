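"""Private-allele filtering, channel designs and the mixed-logit fits."""

import itertools

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import expit, gammaln, logsumexp

from oxbowflow import channel_test as ct
from oxbowflow.assignment import HaplogroupAssignment
from oxbowflow.channel_test import _design_arrays, _laplace_loglik
from oxbowflow.study_io import GenotypeTable, SiteMetadata


def table_from_rows(rows, sites, loci=("A",)):
    arr = np.asarray(rows, dtype=np.int32).reshape(len(rows), len(loci), 2)
    return GenotypeTable(
        tuple(f"i{k}" for k in range(len(rows))), tuple(sites), loci, arr
    )


# ---------------------------------------------------------------------------
# private alleles and the design
# ---------------------------------------------------------------------------


class TestPrivateAlleles:
    def test_identical_allele_sets_give_no_records(self):
        t = table_from_rows([[10, 12]] * 4 + [[10, 12]] * 4, ["w"] * 4 + ["e"] * 4)
        assert ct.find_private_alleles(t, "w", "e") == []

    def test_frequencies_and_threshold_flags(self):
        rows = [[14, 10], [10, 12], [10, 12], [10, 12], [12, 12]] + [[10, 12]] * 5
        t = table_from_rows(rows, ["w"] * 5 + ["e"] * 5)
        (rec,) = ct.find_private_alleles(t, "w", "e")
        assert rec.allele == 14 and rec.origin == "west"
        assert rec.freq_pure == pytest.approx(0.1)
        assert rec.freq_overall == pytest.approx(0.05)
        assert not rec.passed_prevalence and not rec.passed_overall

    def test_prevalence_boundary_is_inclusive(self):
        rows = [[14, 10]] * 3 + [[10, 12]] * 17  # 3/40 copies... build exact 15%
        # 20 individuals west: 6 copies of 14 out of 40 = 0.15 exactly
        rows = [[14, 14]] * 3 + [[10, 12]] * 17
        t = table_from_rows(rows + [[10, 12]] * 10, ["w"] * 20 + ["e"] * 10)
        (rec,) = ct.find_private_alleles(t, "w", "e")
        assert rec.freq_pure == pytest.approx(0.15)
        assert rec.passed_prevalence

    def test_one_per_locus_keeps_highest_overall_frequency(self):
        recs = [
            ct.PrivateAlleleRecord("L1", 10, "west", 0.3, 0.15, True, True, group_id="L1:10"),
            ct.PrivateAlleleRecord("L1", 14, "west", 0.2, 0.25, True, True, group_id="L1:14"),
            ct.PrivateAlleleRecord("L2", 11, "east", 0.4, 0.12, True, True, group_id="L2:11"),
        ]
        sel = ct.filter_diagnostic(recs)
        assert [(r.locus, r.allele) for r in sel] == [("L1", 14), ("L2", 11)]
        assert all(r.selected for r in sel)

    def test_tie_on_overall_frequency_takes_lower_allele_code(self):
        recs = [
            ct.PrivateAlleleRecord("L1", 18, "west", 0.3, 0.2, True, True, group_id="a"),
            ct.PrivateAlleleRecord("L1", 12, "west", 0.3, 0.2, True, True, group_id="b"),
        ]
        (sel,) = ct.filter_diagnostic(recs)
        assert sel.allele == 12


class TestMtdnaPseudoalleles:
    def _assignments(self):
        out = []
        for k, (site, group) in enumerate(
            [("w", "west")] * 4 + [("e", "east")] * 4 + [("c", "west")] * 2 + [("c", "east")] * 2
        ):
            out.append(HaplogroupAssignment(f"i{k}", group, 0.0, 0.1))
        site_of = {
            f"i{k}": s
            for k, (s, _) in enumerate(
                [("w", "")] * 4 + [("e", "")] * 4 + [("c", "")] * 4
            )
        }
        return out, site_of

    def test_mirrored_records_share_one_group(self):
        a, site_of = self._assignments()
        recs = ct.add_mtdna_pseudoalleles(a, site_of, "w", "e")
        assert {r.group_id for r in recs} == {ct.MT_LOCUS}
        assert {r.origin for r in recs} == {"west", "east"}
        assert all(r.freq_pure == 1.0 for r in recs)

    def test_mirrored_counts_conserve_sample_size(self):
        a, site_of = self._assignments()
        recs = ct.add_mtdna_pseudoalleles(a, site_of, "w", "e")
        sites = [
            SiteMetadata("w", "pure", "none", "west", "west"),
            SiteMetadata("e", "pure", "none", "east", "east"),
            SiteMetadata("c", "cis", "north", "east", "west"),
        ]
        t = table_from_rows([[10, 10]] * 12, ["w"] * 4 + ["e"] * 4 + ["c"] * 4)
        rows = ct.build_design(recs, sites, t, assignments=a)
        by_site = {}
        for r in rows:
            by_site.setdefault(r.site_id, []).append(r)
        for site, pair in by_site.items():
            assert sum(r.k for r in pair) == pair[0].n

    def test_all_unassigned_is_an_error(self):
        a = [HaplogroupAssignment("i0", "unassigned", 0.1, 0.1)]
        with pytest.raises(ValueError):
            ct.add_mtdna_pseudoalleles(a, {"i0": "w"}, "w", "e")


class TestBuildDesign:
    def _fixture(self):
        sites = [
            SiteMetadata("w", "pure", "none", "west", "west"),
            SiteMetadata("e", "pure", "none", "east", "east"),
            SiteMetadata("c", "cis", "north", "east", "west"),
        ]
        rows = (
            [[14, 14], [14, 10], [10, 10], [10, 12]]
            + [[12, 12]] * 4
            + [[14, 12], [10, 10], [12, 12], [12, 12]]
        )
        t = table_from_rows(rows, ["w"] * 4 + ["e"] * 4 + ["c"] * 4)
        rec = ct.PrivateAlleleRecord(
            "A", 14, "west", 0.375, 0.25, True, True, True, "A:14"
        )
        return sites, t, rec

    def test_cis_native_flags_follow_the_two_channels(self):
        sites, t, rec = self._fixture()
        rows = ct.build_design([rec], sites, t)
        cis = next(r for r in rows if r.site_id == "c")
        assert cis.native_historical == 1 and cis.native_current == 0
        assert cis.k == 1 and cis.n == 4

    def test_zero_rows_are_retained_and_counts_complete(self):
        sites, t, rec = self._fixture()
        rows = ct.build_design([rec], sites, t)
        assert len(rows) == 3
        east = next(r for r in rows if r.site_id == "e")
        assert east.k == 0 and east.n == 4


# ---------------------------------------------------------------------------
# mixed logit
# ---------------------------------------------------------------------------


def agq_marginal_loglik(params, k, n, x, li, gi, nl, ng, nodes=20):
    """Independent adaptive Gauss-Hermite oracle: its own Newton mode
    search and a Cholesky-scaled full product grid."""
    b0, b1, lsl, lsg = params
    sl2, sg2 = np.exp(2 * lsl), np.exp(2 * lsg)
    q = nl + ng
    dinv = np.concatenate([np.full(nl, 1 / sl2), np.full(ng, 1 / sg2)])
    zl, zg = li, nl + gi
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    def joint(u):
        e = b0 + b1 * x + u[zl] + u[zg]
        return (
            (const + k * e - n * np.logaddexp(0, e)).sum()
            - 0.5 * (dinv * u * u).sum()
            - 0.5 * nl * np.log(2 * np.pi * sl2)
            - 0.5 * ng * np.log(2 * np.pi * sg2)
        )

    u = np.zeros(q)
    for _ in range(200):
        e = b0 + b1 * x + u[zl] + u[zg]
        p = expit(e)
        w = n * p * (1 - p)
        r = k - n * p
        g = np.zeros(q)
        np.add.at(g, zl, r)
        np.add.at(g, zg, r)
        g -= dinv * u
        H = np.zeros((q, q))
        for a, b in ((zl, zl), (zl, zg), (zg, zl), (zg, zg)):
            np.add.at(H, (a, b), w)
        H[np.diag_indices(q)] += dinv
        step = np.linalg.solve(H, g)
        u = u + step
        if np.abs(step).max() < 1e-12:
            break
    L = np.linalg.cholesky(H)
    xs, ws = hermegauss(nodes)
    logw = np.log(ws)
    terms = []
    for idx in itertools.product(range(nodes), repeat=q):
        z = np.array([xs[i] for i in idx])
        uu = u + np.linalg.solve(L.T, z)
        terms.append(sum(logw[i] for i in idx) + joint(uu) + 0.5 * (z * z).sum())
    return logsumexp(terms) - np.sum(np.log(np.diag(L)))


def crossed_rows(seed=0, ntot=400, effect=0.2, lats=("a", "b"), grps=("g1", "g2")):
    rng = np.random.default_rng(seed)
    rows = []
    for i, (lat, gr) in enumerate([(l, g) for l in lats for g in grps]):
        for x in (0, 1):
            k = int(rng.binomial(ntot, 0.3 + effect * x))
            rows.append(ct.ChannelDesignRow(f"s{i}{x}", gr, k, ntot, x, x, lat))
    return rows


class TestMixedLogit:
    @pytest.mark.parametrize("params", [
        (-0.6, 0.7, np.log(0.3), np.log(0.25)),
        (-0.2, 0.0, np.log(0.15), np.log(0.4)),
    ])
    def test_laplace_matches_adaptive_quadrature(self, params):
        rows = crossed_rows()
        k, n, x, li, gi, nl, ng = _design_arrays(rows, "historical")
        lap = _laplace_loglik(list(params), k, n, x, li, gi, nl, ng)
        quad = agq_marginal_loglik(list(params), k, n, x, li, gi, nl, ng)
        assert abs(lap - quad) < 1e-3

    def test_reference_glmm_implementation_agrees(self):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(2)
        rows = []
        for i, (lat, gr) in enumerate(
            [(l, g) for l in ("a", "b", "c") for g in ("g1", "g2", "g3", "g4")]
        ):
            for x in (0, 1):
                p = expit(-0.8 + 0.9 * x + rng.normal(0, 0.3))
                rows.append(
                    ct.ChannelDesignRow(f"s{i}{x}", gr, int(rng.binomial(60, p)), 60, x, x, lat)
                )
        fit = ct.fit_mixed_logit(rows, "historical")
        data = "".join(
            f"{r.k}\t{r.n}\t{r.native_historical}\t{r.latitude}\t{r.group_id}\n"
            for r in rows
        )
        rcode = (
            'suppressMessages(library(lme4));'
            'd <- read.table("stdin", header=FALSE, sep="\\t",'
            ' col.names=c("k","n","x","lat","grp"));'
            'm <- glmer(cbind(k, n-k) ~ x + (1|lat) + (1|grp),'
            ' family=binomial, data=d);'
            'cat(sprintf("%.6f %.6f", fixef(m)[2], as.numeric(logLik(m))))'
        )
        res = subprocess.run(
            ["Rscript", "-e", rcode], input=data, capture_output=True, text=True,
            timeout=120,
        )
        beta_r, lnl_r = map(float, res.stdout.split())
        assert fit.coefficient == pytest.approx(beta_r, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(lnl_r, abs=1e-3)

    def test_null_effect_gives_unit_odds_ratio(self):
        rows = crossed_rows(seed=1, effect=0.0, lats=("a", "b", "c"),
                            grps=("g1", "g2", "g3"))
        fit = ct.fit_mixed_logit(rows, "historical")
        assert abs(fit.coefficient) < 0.05
        assert 0.95 < fit.odds_ratio < 1.05

    def test_known_odds_ratio_is_recovered(self):
        # native 0.4 vs non-native 0.2 carrier probability: OR = 8/3
        ors = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            rows = []
            for i, (lat, gr) in enumerate(
                [(l, g) for l in ("a", "b", "c") for g in [f"g{j}" for j in range(7)]]
            ):
                for x in (0, 1):
                    rows.append(
                        ct.ChannelDesignRow(
                            f"s{i}{x}", gr, int(rng.binomial(25, 0.2 + 0.2 * x)),
                            25, x, x, lat,
                        )
                    )
            ors.append(ct.fit_mixed_logit(rows, "historical").odds_ratio)
        assert 2.0 <= float(np.median(ors)) <= 3.5

    def test_separation_is_flagged(self):
        rows = []
        for i, lat in enumerate(("a", "b")):
            for gr in ("g1", "g2"):
                rows.append(ct.ChannelDesignRow(f"s{i}0{gr}", gr, 0, 20, 0, 0, lat))
                rows.append(ct.ChannelDesignRow(f"s{i}1{gr}", gr, 12, 20, 1, 1, lat))
        fit = ct.fit_mixed_logit(rows, "historical")
        assert fit.flagged is not None

    def test_degenerate_designs_are_rejected(self):
        rows = crossed_rows(lats=("a",))
        with pytest.raises(ValueError):
            ct.fit_mixed_logit(rows, "historical")
        rows = [r for r in crossed_rows() if r.native_historical == 1]
        with pytest.raises(ValueError):
            ct.fit_mixed_logit(rows, "historical")


class TestCompareChannels:
    def test_identical_designs_give_exactly_zero_delta_aic(self):
        rows = crossed_rows(seed=3)  # no cis rows: flags agree everywhere
        cmp = ct.compare_channels(rows)
        assert cmp.delta_aic == 0.0

    def test_swapping_west_and_east_labels_preserves_delta_aic(self, default_study):
        dataset, _ = default_study
        t = dataset.genotypes
        recs = ct.find_private_alleles(t, "west_pure", "east_pure")
        sel = ct.filter_diagnostic(recs)
        rows = ct.build_design(sel, list(dataset.analysis_sites), t)
        cmp = ct.compare_channels(rows)
        mirrored = [
            ct.ChannelDesignRow(
                r.site_id, r.group_id, r.k, r.n,
                1 - r.native_historical, 1 - r.native_current, r.latitude, r.is_mtdna,
            )
            for r in rows
        ]
        # relabelling every allele's side of origin flips each site's native
        # flag; the fit is the same model with the predictor complemented
        # (slope sign inverted), so both AICs and the comparison are
        # unchanged
        cmp2 = ct.compare_channels(mirrored)
        assert cmp2.delta_aic == pytest.approx(cmp.delta_aic, abs=0.05)
        assert cmp2.preferred == cmp.preferred
        assert cmp2.fit_historical.coefficient == pytest.approx(
            -cmp.fit_historical.coefficient, abs=0.02
        )

    def test_removing_cis_rows_forces_zero(self, default_study):
        dataset, _ = default_study
        t = dataset.genotypes
        sel = ct.filter_diagnostic(ct.find_private_alleles(t, "west_pure", "east_pure"))
        rows = ct.build_design(sel, list(dataset.analysis_sites), t)
        no_cis = [r for r in rows if r.native_historical == r.native_current]
        cmp = ct.compare_channels(no_cis)
        assert cmp.delta_aic == 0.0
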