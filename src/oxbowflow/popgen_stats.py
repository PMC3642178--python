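"""Diversity indices, disequilibrium tests and pairwise differentiation.

Implements the microsatellite summary statistics of a riverine-barrier
study: Nei's unbiased gene diversity, observed heterozygosity,
Weir–Cockerham F-statistics (within-population f = F_IS and two-population
theta = F_ST), rarefied allelic richness, Guo–Thompson exact tests for
Hardy–Weinberg equilibrium, G-test based linkage-disequilibrium
permutation tests with Bonferroni correction, Hedrick's standardized G'_ST
and Jost's D_est (with the SMOGD-style global estimate across loci), and a
one-level AMOVA used to justify pooling nearby sampling locations.

All estimators are computed from first principles on a
:class:`~oxbowflow.study_io.GenotypeTable`; missing genotypes are excluded
locus-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .study_io import MISSING, GenotypeTable, SiteMetadata

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


class UndefinedStatistic(ValueError):
    """The requested estimator is undefined on these data."""


# ---------------------------------------------------------------------------
# counting helpers
# ---------------------------------------------------------------------------


def _site_block(table: GenotypeTable, site: str) -> np.ndarray:
    mask = table.site_mask(site)
    if not mask.any():
        raise UndefinedStatistic(f"site {site!r} has no individuals")
    return table.alleles[mask]


def locus_allele_counts(table: GenotypeTable, site: str, locus_idx: int) -> dict[int, int]:
    """Gene-copy counts per allele at one site/locus (missing excluded)."""
    block = _site_block(table, site)[:, locus_idx, :]
    genes = block[block[:, 0] != MISSING].ravel()
    vals, counts = np.unique(genes, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def allele_frequencies(table: GenotypeTable, site: str) -> dict[str, dict[int, float]]:
    """Per-locus allele frequency vectors at one site.

    Frequencies sum to 1 per locus; a locus with no scored genotype at the
    site raises, naming the locus.
    """
    out: dict[str, dict[int, float]] = {}
    for l, locus in enumerate(table.loci):
        counts = locus_allele_counts(table, site, l)
        total = sum(counts.values())
        if total == 0:
            raise UndefinedStatistic(
                f"locus {locus} entirely missing at site {site}"
            )
        out[locus] = {a: c / total for a, c in counts.items()}
    return out


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def nei_unbiased_diversity(freqs, n_genes: int) -> float:
    """Nei's unbiased gene diversity H_E = n/(n-1) (1 - sum p_i^2),
    with n the number of gene copies."""
    if n_genes < 2:
        raise UndefinedStatistic("H_E needs at least 2 gene copies")
    p = np.asarray(
        list(freqs.values()) if isinstance(freqs, dict) else freqs, dtype=float
    )
    return float(n_genes / (n_genes - 1) * (1.0 - (p**2).sum()))


def observed_heterozygosity(table: GenotypeTable, site: str) -> tuple[np.ndarray, float]:
    """Per-locus observed heterozygosity (fraction of scored genotypes with
    two distinct alleles) and its mean across scorable loci."""
    block = _site_block(table, site)
    scored = block[:, :, 0] != MISSING
    if not scored.any():
        raise UndefinedStatistic(f"no scored genotypes at {site}")
    het = (block[:, :, 0] != block[:, :, 1]) & scored
    with np.errstate(invalid="ignore"):
        per_locus = het.sum(axis=0) / scored.sum(axis=0)
    return per_locus, float(np.nanmean(per_locus))


def expected_heterozygosity_site(table: GenotypeTable, site: str) -> tuple[np.ndarray, float]:
    """Per-locus Nei unbiased H_E at one site and the mean across loci."""
    out = np.full(table.n_loci, np.nan)
    for l, locus in enumerate(table.loci):
        counts = locus_allele_counts(table, site, l)
        n = sum(counts.values())
        if n >= 2:
            out[l] = nei_unbiased_diversity(
                {a: c / n for a, c in counts.items()}, n
            )
    return out, float(np.nanmean(out))


def _locus_stats(block: np.ndarray, l: int) -> tuple[int, dict[int, float], dict[int, float]]:
    """(n individuals, allele freqs, per-allele heterozygote fraction)."""
    g = block[:, l, :]
    g = g[g[:, 0] != MISSING]
    n = len(g)
    if n == 0:
        return 0, {}, {}
    genes = g.ravel()
    vals, counts = np.unique(genes, return_counts=True)
    freqs = {int(a): c / (2 * n) for a, c in zip(vals, counts)}
    het = {}
    is_het = g[:, 0] != g[:, 1]
    for a in vals:
        het[int(a)] = float((is_het & ((g[:, 0] == a) | (g[:, 1] == a))).mean())
    return n, freqs, het


def fis_weir_cockerham(table: GenotypeTable, site: str) -> tuple[np.ndarray, float]:
    """Weir & Cockerham's small-sample within-population inbreeding
    coefficient f (F_IS), per locus and multilocus.

    Per allele u with sample size n, frequency p and heterozygote fraction
    h: b = n/(n-1) [p(1-p) - (2n-1)/(4n) h], c = h/2, and
    f = 1 - sum(c) / sum(b + c); the multilocus value sums components over
    loci.  Monomorphic loci are undefined per locus and excluded from the
    sums.
    """
    block = _site_block(table, site)
    if len(block) < 2:
        raise UndefinedStatistic("F_IS needs at least 2 individuals")
    per_locus = np.full(table.n_loci, np.nan)
    B = C = 0.0
    for l in range(table.n_loci):
        n, freqs, het = _locus_stats(block, l)
        if n < 2 or len(freqs) < 2:
            continue
        b = c = 0.0
        for a, p in freqs.items():
            h = het[a]
            b += n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            c += h / 2
        if b + c > 0:
            per_locus[l] = 1.0 - c / (b + c)
            B += b
            C += c
    if B + C <= 0:
        raise UndefinedStatistic(f"F_IS undefined at {site}: no polymorphic locus")
    return per_locus, float(1.0 - C / (B + C))


def rarefied_richness(counts, g: int) -> float:
    """Expected allele count in a subsample of ``g`` gene copies
    (hypergeometric rarefaction): sum over alleles of
    1 - C(N - N_i, g) / C(N, g)."""
    c = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=int
    )
    c = c[c > 0]
    N = int(c.sum())
    if g < 1:
        raise UndefinedStatistic("rarefaction depth must be >= 1")
    if g > N:
        raise UndefinedStatistic(f"rarefaction depth {g} exceeds {N} gene copies")

    def log_comb(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    total = 0.0
    for ni in c:
        rest = N - int(ni)
        if rest < g:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(rest, g) - log_comb(N, g))
    return total


def allelic_richness_rarefied(table: GenotypeTable, site: str, g: int) -> float:
    """Rarefied allelic richness at depth ``g`` gene copies, averaged over
    loci with at least ``g`` scored copies at the site."""
    vals = []
    for l in range(table.n_loci):
        counts = locus_allele_counts(table, site, l)
        if sum(counts.values()) >= g:
            vals.append(rarefied_richness(counts, g))
    if not vals:
        raise UndefinedStatistic(
            f"no locus at {site} has {g} scored gene copies"
        )
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Hardy-Weinberg and linkage disequilibrium
# ---------------------------------------------------------------------------


def _genotype_log_prob(code_sorted: np.ndarray, n_het: np.ndarray) -> np.ndarray:
    """log conditional probability (up to a constant) of genotype tables.

    ``code_sorted`` is (reps, n) of sorted genotype codes; the conditional
    probability of a table given allele counts is proportional to
    2^het / prod(genotype-count factorials).
    """
    reps, n = code_sorted.shape
    change = np.ones((reps, n), dtype=bool)
    change[:, 1:] = code_sorted[:, 1:] != code_sorted[:, :-1]
    j = np.broadcast_to(np.arange(n), (reps, n))
    last_change = np.maximum.accumulate(np.where(change, j, 0), axis=1)
    run_pos = j - last_change + 1  # running count of the current genotype
    return n_het * LN2 - np.log(run_pos).sum(axis=1)


def hwe_exact_test(
    table: GenotypeTable,
    site: str,
    locus: str,
    mc_reps: int = 100_000,
    seed: int = 0,
    force_mc: bool = False,
) -> float:
    """Exact test for Hardy–Weinberg equilibrium at one site and locus.

    Uses the probability-ordering rejection region.  With two alleles the
    full conditional distribution is enumerated (the test is then exact);
    with more alleles a Guo–Thompson Monte-Carlo estimate with ``mc_reps``
    shuffles of the gene-copy vector is returned.  Monomorphic loci give
    p = 1 with a warning.
    """
    l = table.loci.index(locus)
    block = _site_block(table, site)
    g = block[:, l, :]
    g = g[g[:, 0] != MISSING]
    n = len(g)
    if n < 3:
        raise UndefinedStatistic("HWE test needs >= 3 scored individuals")
    alleles = np.unique(g)
    k = len(alleles)
    if k < 2:
        logger.warning("HWE test at %s/%s: monomorphic locus, p = 1", site, locus)
        return 1.0

    if k == 2 and not force_mc:
        a_count = int((g == alleles[0]).sum())
        h_obs = int((g[:, 0] != g[:, 1]).sum())
        return _hwe_two_allele_exact(n, a_count, h_obs)

    # Guo-Thompson Monte Carlo
    rng = np.random.default_rng(seed)
    recode = np.searchsorted(alleles, g)
    lo = recode.min(axis=1)
    hi = recode.max(axis=1)
    obs_codes = np.sort(lo * k + hi)[None, :]
    obs_lp = _genotype_log_prob(obs_codes, np.array([(lo != hi).sum()]))[0]

    genes = recode.ravel()
    pool = np.broadcast_to(genes, (mc_reps, 2 * n)).copy()
    pool = rng.permuted(pool, axis=1)
    a = pool[:, 0::2]
    b = pool[:, 1::2]
    lo_p = np.minimum(a, b)
    hi_p = np.maximum(a, b)
    codes = np.sort(lo_p * k + hi_p, axis=1)
    lps = _genotype_log_prob(codes, (a != b).sum(axis=1))
    return float((1 + (lps <= obs_lp + 1e-9).sum()) / (mc_reps + 1))


def _hwe_two_allele_exact(n: int, n_a: int, h_obs: int) -> float:
    """Exact two-allele HWE p-value by enumerating heterozygote counts."""
    n_b = 2 * n - n_a
    h_min = max(n_a - 2 * (n_a // 2) , 0)  # parity of n_a
    hs = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    # log P(h) up to constant: 2^h / (naa! nab! nbb!)
    naa = (n_a - hs) // 2
    nbb = (n_b - hs) // 2
    lp = hs * LN2 - gammaln(naa + 1) - gammaln(hs + 1) - gammaln(nbb + 1)
    lp -= lp.max()
    p = np.exp(lp)
    p /= p.sum()
    obs = p[hs == h_obs][0]
    return float(p[p <= obs + 1e-12].sum())


def ld_permutation_test(
    table: GenotypeTable,
    site: str,
    locus_pair: tuple[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Genotypic linkage-disequilibrium test for one locus pair at a site.

    The statistic is the G statistic of the two-locus genotype contingency
    table; the null is built by permuting one locus's genotypes across
    individuals; p = (1 + #{G_perm >= G_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful test")
    la, lb = (table.loci.index(x) for x in locus_pair)
    block = _site_block(table, site)
    ga, gb = block[:, la, :], block[:, lb, :]
    keep = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    ga, gb = ga[keep], gb[keep]
    if len(ga) < 3:
        raise UndefinedStatistic("LD test needs >= 3 doubly scored individuals")

    def genotype_codes(g: np.ndarray) -> np.ndarray:
        pair = np.sort(g, axis=1)
        _, codes = np.unique(pair[:, 0] * 10_000 + pair[:, 1], return_inverse=True)
        return codes

    ca, cb = genotype_codes(ga), genotype_codes(gb)
    ka, kb = ca.max() + 1, cb.max() + 1
    if ka < 2 or kb < 2:
        raise UndefinedStatistic("both loci must be polymorphic at the site")
    n = len(ca)

    def g_stat(cb_vec: np.ndarray) -> float:
        obs = np.bincount(ca * kb + cb_vec, minlength=ka * kb).reshape(ka, kb)
        rows = obs.sum(axis=1, keepdims=True)
        cols = obs.sum(axis=0, keepdims=True)
        exp = rows * cols / n
        nz = obs > 0
        return float(2.0 * (obs[nz] * np.log(obs[nz] / exp[nz])).sum())

    g_obs = g_stat(cb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += g_stat(rng.permutation(cb)) >= g_obs - 1e-12
    logger.debug("ld_permutation_test %s %s: %d permutations", site, locus_pair, n_perm)
    return float((1 + count) / (n_perm + 1))


@dataclass(frozen=True)
class BonferroniResult:
    flags: np.ndarray
    threshold: float
    family_size: int


def bonferroni(pvals, alpha: float = 0.05) -> BonferroniResult:
    """Bonferroni-adjusted significance flags: p <= alpha/m (inclusive)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty test family")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    thr = alpha / p.size
    return BonferroniResult(p <= thr + 1e-15, thr, p.size)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta and differentiation metrics
# ---------------------------------------------------------------------------


def _wc_components(blocks: list[np.ndarray], n_loci: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components a, b, c per locus,
    summed over alleles, for r = len(blocks) populations."""
    r = len(blocks)
    A = np.zeros(n_loci)
    B = np.zeros(n_loci)
    C = np.zeros(n_loci)
    for l in range(n_loci):
        stats = [_locus_stats(blk, l) for blk in blocks]
        ns = np.array([s[0] for s in stats], dtype=float)
        if (ns < 1).any():
            continue
        alleles = sorted({a for s in stats for a in s[1]})
        if len(alleles) < 2:
            continue
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        if nbar <= 1 or nc <= 0:
            continue
        for u in alleles:
            p_i = np.array([s[1].get(u, 0.0) for s in stats])
            h_i = np.array([s[2].get(u, 0.0) for s in stats])
            pbar = (ns * p_i).sum() / (r * nbar)
            s2 = (ns * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            A[l] += a
            B[l] += b
            C[l] += c
    return A, B, C


def _theta_from_components(A, B, C) -> float:
    denom = (A + B + C).sum()
    if denom == 0:
        raise UndefinedStatistic("theta undefined: no variation")
    return float(A.sum() / denom)


def pairwise_fst(
    table: GenotypeTable,
    site_a: str,
    site_b: str,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, float, float | None]:
    """Weir–Cockerham theta between two sites.

    Returns per-locus theta (NaN where undefined), the multilocus value
    (variance components summed over loci) and, when ``n_perm > 0``, a
    p-value from permuting individuals between the sites.
    """
    blocks = [_site_block(table, site_a), _site_block(table, site_b)]
    if min(len(b) for b in blocks) < 2:
        raise UndefinedStatistic("pairwise theta needs >= 2 individuals per site")
    A, B, C = _wc_components(blocks, table.n_loci)
    theta = _theta_from_components(A, B, C)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(A + B + C != 0, A / (A + B + C), np.nan)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        combined = np.concatenate(blocks, axis=0)
        n_a = len(blocks[0])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(combined))
            pa, pb = combined[perm[:n_a]], combined[perm[n_a:]]
            try:
                t = _theta_from_components(*_wc_components([pa, pb], table.n_loci))
            except UndefinedStatistic:
                t = 0.0
            count += t >= theta - 1e-12
        p = float((1 + count) / (n_perm + 1))
    return per_locus, theta, p


def _nei_chesser(blocks: list[np.ndarray], l: int) -> tuple[float, float] | None:
    """Nei & Chesser (1983) unbiased (H_S, H_T) at one locus, k pops."""
    stats = [_locus_stats(blk, l) for blk in blocks]
    ns = np.array([s[0] for s in stats], dtype=float)
    if (ns < 2).any():
        return None
    k = len(blocks)
    ntilde = k / (1.0 / ns).sum()
    alleles = sorted({a for s in stats for a in s[1]})
    if len(alleles) < 2:
        return None
    P = np.array([[s[1].get(u, 0.0) for u in alleles] for s in stats])
    # mean observed heterozygosity across pops
    ho = 0.0
    for s in stats:
        # per-allele het fractions double count: each het genotype counted
        # for both its alleles, so total het fraction = sum/2
        ho += sum(s[2].values()) / 2.0
    ho /= k
    hs_raw = 1.0 - (P**2).sum(axis=1).mean()
    hs = ntilde / (ntilde - 1) * (hs_raw - ho / (2 * ntilde))
    pbar = P.mean(axis=0)
    ht = 1.0 - (pbar**2).sum() + hs / (k * ntilde) - ho / (2 * k * ntilde)
    return hs, ht


def gst_hedrick(table: GenotypeTable, site_a: str, site_b: str) -> tuple[np.ndarray, float]:
    """Hedrick's standardized G'_ST = G_ST / G_ST(max) for a site pair,
    per locus and global (from across-locus mean H_S and H_T)."""
    blocks = [_site_block(table, site_a), _site_block(table, site_b)]
    k = 2.0
    per_locus = np.full(table.n_loci, np.nan)
    hs_list, ht_list = [], []
    for l in range(table.n_loci):
        pair = _nei_chesser(blocks, l)
        if pair is None:
            continue
        hs, ht = pair
        hs_list.append(hs)
        ht_list.append(ht)
        if ht > 0 and hs < 1:
            gst = (ht - hs) / ht
            gmax = (k - 1) * (1 - hs) / (k - 1 + hs)
            per_locus[l] = gst / gmax if gmax > 0 else np.nan
    if not hs_list:
        raise UndefinedStatistic("G'_ST undefined: no usable locus")
    hs_m, ht_m = float(np.mean(hs_list)), float(np.mean(ht_list))
    if hs_m >= 1.0:
        raise UndefinedStatistic("G'_ST undefined: H_S = 1")
    if ht_m <= 0:
        return per_locus, 0.0
    gst = (ht_m - hs_m) / ht_m
    gmax = (k - 1) * (1 - hs_m) / (k - 1 + hs_m)
    return per_locus, float(gst / gmax)


def d_est_jost(table: GenotypeTable, site_a: str, site_b: str) -> tuple[np.ndarray, float, float]:
    """Jost's D_est per locus plus global estimates for a site pair.

    Per locus: D = [(H_T - H_S)/(1 - H_S)] * k/(k-1), k = 2, with
    Nei–Chesser unbiased estimators.  The global value floors negative
    per-locus values at 0 and applies the SMOGD-style variance-adjusted
    harmonic mean; the plain arithmetic mean is returned alongside.
    """
    blocks = [_site_block(table, site_a), _site_block(table, site_b)]
    per_locus = np.full(table.n_loci, np.nan)
    for l in range(table.n_loci):
        pair = _nei_chesser(blocks, l)
        if pair is None:
            continue
        hs, ht = pair
        if hs < 1.0:
            per_locus[l] = (ht - hs) / (1.0 - hs) * 2.0
    vals = per_locus[~np.isnan(per_locus)]
    if vals.size == 0:
        raise UndefinedStatistic("D_est undefined: all loci monomorphic")
    floored = np.maximum(vals, 0.0)
    mean = float(floored.mean())
    if mean <= 0:
        harmonic = 0.0
    else:
        var = float(floored.var())
        harmonic = 1.0 / (1.0 / mean + var * (1.0 / mean) ** 3)
    return per_locus, float(harmonic), mean


@dataclass(frozen=True)
class DivergenceResult:
    """Multilocus differentiation between one site pair."""

    site_a: str
    site_b: str
    fst: float
    gst_prime: float
    d_est: float
    d_est_mean: float
    p_value: float | None


def divergence_pair(
    table: GenotypeTable,
    site_a: str,
    site_b: str,
    n_perm: int = 0,
    seed: int = 0,
) -> DivergenceResult:
    """All three differentiation metrics for one site pair."""
    _, theta, p = pairwise_fst(table, site_a, site_b, n_perm=n_perm, seed=seed)
    _, gp = gst_hedrick(table, site_a, site_b)
    _, d_h, d_m = d_est_jost(table, site_a, site_b)
    return DivergenceResult(site_a, site_b, theta, gp, d_h, d_m, p)


def divergence_table(
    table: GenotypeTable,
    site_ids: list[str],
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise divergence for every pair among ``site_ids``."""
    rows = []
    for i, a in enumerate(site_ids):
        for b in site_ids[i + 1 :]:
            r = divergence_pair(table, a, b, n_perm=n_perm, seed=seed)
            rows.append(
                {
                    "site_a": a,
                    "site_b": b,
                    "fst": r.fst,
                    "gst_prime": r.gst_prime,
                    "d_est": r.d_est,
                    "d_est_mean": r.d_est_mean,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AMOVA pooling check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolingCheck:
    parent_site: str
    locations: tuple[str, ...]
    theta: float
    p_value: float
    pooling_recommended: bool


def amova_pooling_check(
    raw_table: GenotypeTable,
    parent: SiteMetadata,
    n_perm: int = 999,
    seed: int = 0,
) -> PoolingCheck:
    """One-level AMOVA among the member sampling locations of one site.

    The among-location statistic is multilocus Weir–Cockerham theta; the
    null distribution permutes individuals among locations.  Pooling is
    recommended iff p > 0.05.
    """
    locations = [parent.site_id, *parent.members]
    locations = [s for s in locations if s in raw_table.site_ids]
    if len(locations) < 2:
        raise UndefinedStatistic(
            f"{parent.site_id}: pooling check needs >= 2 member locations"
        )
    blocks = [_site_block(raw_table, s) for s in locations]
    for s, b in zip(locations, blocks):
        if len(b) == 0:
            raise UndefinedStatistic(f"location {s} has no individuals")
    theta = _theta_from_components(*_wc_components(blocks, raw_table.n_loci))
    sizes = np.array([len(b) for b in blocks])
    combined = np.concatenate(blocks, axis=0)
    bounds = np.cumsum(sizes)[:-1]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(combined))
        parts = np.split(combined[perm], bounds)
        try:
            t = _theta_from_components(*_wc_components(parts, raw_table.n_loci))
        except UndefinedStatistic:
            t = 0.0
        count += t >= theta - 1e-12
    p = float((1 + count) / (n_perm + 1))
    return PoolingCheck(parent.site_id, tuple(locations), theta, p, p > 0.05)


# ---------------------------------------------------------------------------
# Table-1-style summary
# ---------------------------------------------------------------------------


def min_gene_copies(table: GenotypeTable, site_ids: list[str] | None = None) -> int:
    """Smallest number of scored gene copies over sites x loci."""
    sites = site_ids or list(table.site_ids)
    best = None
    for s in sites:
        block = _site_block(table, s)
        scored = (block[:, :, 0] != MISSING).sum(axis=0) * 2
        m = int(scored.min())
        best = m if best is None else min(best, m)
    return best or 0


def diversity_summary(
    table: GenotypeTable,
    g_rarefy: int = 40,
    g_star: int | None = None,
    excluded_loci: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-site diversity indices across loci (a Table-1-style report):
    sample size N, mean allele number A_N, rarefied richness A_R (depth
    ``g_rarefy``, capped at the site's scored copies) and A_R* (depth
    ``g_star``, default the global minimum), Nei unbiased H_E, observed
    H_O, and multilocus Weir–Cockerham F_IS."""
    if excluded_loci:
        table = table.drop_loci(excluded_loci)
    if g_star is None:
        g_star = min_gene_copies(table)
    rows = []
    for site in table.site_ids:
        block = _site_block(table, site)
        n = len(block)
        a_n = []
        for l in range(table.n_loci):
            counts = locus_allele_counts(table, site, l)
            if counts:
                a_n.append(len(counts))
        site_min = int(((block[:, :, 0] != MISSING).sum(axis=0) * 2).min())
        _, he = expected_heterozygosity_site(table, site)
        _, ho = observed_heterozygosity(table, site)
        try:
            _, fis = fis_weir_cockerham(table, site)
        except UndefinedStatistic:
            fis = np.nan
        rows.append(
            {
                "site": site,
                "N": n,
                "A_N": float(np.mean(a_n)),
                "A_R": allelic_richness_rarefied(table, site, min(g_rarefy, site_min)),
                "A_R_star": allelic_richness_rarefied(table, site, min(g_star, site_min)),
                "H_E": he,
                "H_O": ho,
                "F_IS": fis,
            }
        )
    return pd.DataFrame(rows).set_index("site")


def disequilibrium_report(
    table: GenotypeTable,
    mc_reps: int = 10_000,
    ld_perm: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """HWE exact tests per site x locus (and optional LD tests per site x
    locus pair) with a family-wide Bonferroni correction."""
    hwe_rows = []
    for site in table.site_ids:
        for locus in table.loci:
            try:
                p = hwe_exact_test(table, site, locus, mc_reps=mc_reps, seed=seed)
            except UndefinedStatistic:
                continue
            hwe_rows.append({"site": site, "locus": locus, "p": p})
    hwe = pd.DataFrame(hwe_rows)
    out = {"hwe": hwe}
    if len(hwe):
        bf = bonferroni(hwe["p"].to_numpy(), alpha)
        hwe["significant"] = bf.flags
        out["hwe_threshold"] = bf.threshold
        out["hwe_significant"] = int(bf.flags.sum())
        out["hwe_total"] = bf.family_size
    if ld_perm >= 100:
        ld_rows = []
        for site in table.site_ids:
            for i, la in enumerate(table.loci):
                for lb in table.loci[i + 1 :]:
                    try:
                        p = ld_permutation_test(
                            table, site, (la, lb), n_perm=ld_perm, seed=seed
                        )
                    except UndefinedStatistic:
                        continue
                    ld_rows.append(
                        {"site": site, "locus_a": la, "locus_b": lb, "p": p}
                    )
        ld = pd.DataFrame(ld_rows)
        if len(ld):
            bf = bonferroni(ld["p"].to_numpy(), alpha)
            ld["significant"] = bf.flags
            out["ld_threshold"] = bf.threshold
        out["ld"] = ld
    return out
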