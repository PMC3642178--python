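"""mtDNA haplogroup assignment and Bayesian admixture clustering.

Haplogroups: each individual's mtDNA sequence is assigned to the western
or eastern clade by uncorrected p-distance (pairwise deletion of gaps and
Ns) to the nearest reference haplotype from the corresponding pure site;
an exact tie leaves the individual unassigned.  With deeply divergent,
reciprocally monophyletic haplogroups this nearest-reference rule gives
the same clade decision as a full likelihood tree.

Clustering: a Pritchard-style admixture model over unlinked codominant
loci.  Each allele copy of individual i has a latent cluster origin z;
cluster allele frequencies P get a Dirichlet(lambda=1) prior and
admixture proportions Q a Dirichlet(alpha) prior.  A Gibbs sampler
alternates z | P,Q ; P | z ; Q | z, optionally updating a shared alpha by
Metropolis.  The model log-likelihood is estimated from the post-burnin
trace as mean(lnL) - var(lnL)/2, and K is selected both by that estimate
and by the Evanno delta-K statistic across replicate runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_io import MISSING, GenotypeTable, HaplotypeSet

logger = logging.getLogger(__name__)

_VALID = frozenset(b"ACGT")


# ---------------------------------------------------------------------------
# haplogroups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplogroupAssignment:
    individual_id: str
    haplogroup: str  # "west" / "east" / "unassigned"
    dist_west: float
    dist_east: float


def _pdist_matrix(queries: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Min uncorrected p-distance from each query to a reference panel,
    with pairwise deletion of non-ACGT positions."""
    q_ok = np.isin(queries, np.frombuffer(b"ACGT", dtype=np.uint8))
    r_ok = np.isin(refs, np.frombuffer(b"ACGT", dtype=np.uint8))
    out = np.empty((len(queries), len(refs)))
    for j in range(len(refs)):
        both = q_ok & r_ok[j]
        diff = (queries != refs[j]) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[:, j] = np.where(denom > 0, diff.sum(axis=1) / denom, np.inf)
    return out.min(axis=1)


def assign_haplogroups(
    haps: HaplotypeSet,
    west_refs: HaplotypeSet,
    east_refs: HaplotypeSet,
) -> list[HaplogroupAssignment]:
    """Assign every sequence to the clade of its nearest pure-site
    reference; exact ties are left unassigned."""
    if len(west_refs) == 0 or len(east_refs) == 0:
        raise ValueError("both reference sets must be non-empty")
    if not (
        haps.alignment_length
        == west_refs.alignment_length
        == east_refs.alignment_length
    ):
        raise ValueError("alignment lengths differ between query and references")
    dw = _pdist_matrix(haps.seqs, west_refs.seqs)
    de = _pdist_matrix(haps.seqs, east_refs.seqs)
    out = []
    for i, ind in enumerate(haps.ids):
        if np.isclose(dw[i], de[i], rtol=0.0, atol=1e-12):
            group = "unassigned"
        else:
            group = "west" if dw[i] < de[i] else "east"
        out.append(HaplogroupAssignment(ind, group, float(dw[i]), float(de[i])))
    return out


def haplogroup_site_composition(
    assignments: list[HaplogroupAssignment],
    site_of: dict[str, str],
) -> pd.DataFrame:
    """Per-site west/east/unassigned fractions (west + east = 1 minus the
    unassigned fraction)."""
    rows: dict[str, dict[str, int]] = {}
    for a in assignments:
        site = site_of[a.individual_id]
        d = rows.setdefault(site, {"west": 0, "east": 0, "unassigned": 0})
        d[a.haplogroup] += 1
    recs = []
    for site, d in rows.items():
        n = sum(d.values())
        recs.append(
            {
                "site": site,
                "n": n,
                "west": d["west"] / n,
                "east": d["east"] / n,
                "unassigned": d["unassigned"] / n,
            }
        )
    return pd.DataFrame(recs).set_index("site").sort_index()


# ---------------------------------------------------------------------------
# admixture model
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class AncestryResult:
    """One admixture run: cluster count K, per-individual admixture Q,
    cluster allele frequencies, and the model log-likelihood estimate."""

    k: int
    individuals: tuple[str, ...]
    q_matrix: np.ndarray  # (n, K)
    cluster_freqs: list[np.ndarray]  # per locus (K, n_alleles)
    log_likelihood: float
    alpha: float
    seed: int

    def site_means(self, site_of: dict[str, str]) -> pd.DataFrame:
        df = pd.DataFrame(
            self.q_matrix,
            index=list(self.individuals),
            columns=[f"cluster_{j + 1}" for j in range(self.k)],
        )
        df["site"] = [site_of[i] for i in self.individuals]
        return df.groupby("site").mean()


def _recode(table: GenotypeTable) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Flatten genotypes to per-copy allele indices; -1 marks missing."""
    codes = np.full((table.n_individuals, table.n_loci, 2), -1, dtype=np.int64)
    allele_maps = []
    for l in range(table.n_loci):
        col = table.alleles[:, l, :]
        present = col[col > 0]
        alleles = np.unique(present)
        allele_maps.append(alleles)
        for s in range(2):
            scored = col[:, s] > 0
            codes[scored, l, s] = np.searchsorted(alleles, col[scored, s])
    observed = codes >= 0
    return codes, allele_maps, observed


def admixture_mcmc(
    table: GenotypeTable,
    k: int,
    n_sweeps: int = 20_000,
    burnin: int = 5_000,
    seed: int = 0,
    alpha_mode: str = "fixed",
    anchor_ids: tuple[str, ...] | None = None,
) -> AncestryResult:
    """One Gibbs-sampler run of the admixture model.

    ``alpha_mode`` is ``"fixed"`` (alpha = 1) or ``"infer"`` (shared alpha
    updated by Metropolis).  Cluster labels are canonicalized by descending
    mean Q among ``anchor_ids`` (intended: the west-pure individuals), so
    replicate runs are comparable without external label matching.
    Identical inputs and seed reproduce the chain exactly.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if n_sweeps <= burnin:
        raise ValueError("n_sweeps must exceed burnin")
    if alpha_mode not in ("fixed", "infer"):
        raise ValueError("alpha_mode must be 'fixed' or 'infer'")
    rng = np.random.default_rng(seed)
    codes, allele_maps, observed = _recode(table)
    n, n_loci, _ = codes.shape
    if k == 1:
        # forced: every individual fully in the single cluster
        freqs = []
        for l, alleles in enumerate(allele_maps):
            c = np.bincount(codes[:, l, :][observed[:, l, :]], minlength=len(alleles))
            freqs.append((c / max(c.sum(), 1))[None, :])
        ll = _model_loglik(codes, observed, np.ones((n, 1)), freqs)
        return AncestryResult(
            1, table.individuals, np.ones((n, 1)), freqs, ll, 1.0, seed
        )

    alpha = 1.0
    q = rng.dirichlet(np.ones(k), size=n)
    p = [rng.dirichlet(np.ones(len(a)), size=k) for a in allele_maps]

    q_sum = np.zeros((n, k))
    p_sum = [np.zeros_like(pl) for pl in p]
    ll_trace = []
    alpha_trace = []
    kept = 0
    flat_obs = observed.reshape(n, -1)

    for sweep in range(n_sweeps):
        # P(z = j) per allele copy: q_ij * p_j,l,allele
        like = np.empty((n, n_loci, 2, k))
        for l in range(n_loci):
            pl = p[l]  # (k, n_alleles)
            c = codes[:, l, :]
            safe = np.where(c >= 0, c, 0)
            like[:, l, :, :] = pl.T[safe]  # (n, 2, k)
        probs = like * q[:, None, None, :]
        tot = probs.sum(axis=3, keepdims=True)
        probs = np.where(tot > 0, probs / np.maximum(tot, 1e-300), 1.0 / k)
        # sample z by inverse CDF
        u = rng.random((n, n_loci, 2, 1))
        z = (probs.cumsum(axis=3) < u).sum(axis=3)
        z[~observed] = -1

        # update P | z
        for l in range(n_loci):
            na = len(allele_maps[l])
            counts = np.zeros((k, na))
            for s in range(2):
                sel = observed[:, l, s]
                np.add.at(counts, (z[sel, l, s], codes[sel, l, s]), 1.0)
            p[l] = rng.gamma(counts + 1.0)
            p[l] /= p[l].sum(axis=1, keepdims=True)

        # update Q | z
        zc = np.zeros((n, k))
        zz = z.reshape(n, -1)
        for j in range(k):
            zc[:, j] = ((zz == j) & flat_obs).sum(axis=1)
        q = rng.gamma(zc + alpha)
        q /= q.sum(axis=1, keepdims=True)

        if alpha_mode == "infer":
            alpha = _update_alpha(rng, alpha, q)

        if sweep >= burnin:
            kept += 1
            q_sum += q
            for l in range(n_loci):
                p_sum[l] += p[l]
            ll_trace.append(_model_loglik(codes, observed, q, p))
            alpha_trace.append(alpha)

    q_mean = q_sum / kept
    p_mean = [ps / kept for ps in p_sum]
    lls = np.asarray(ll_trace)
    model_ll = float(lls.mean() - lls.var() / 2.0)

    order = _canonical_order(table, q_mean, anchor_ids)
    q_mean = q_mean[:, order]
    p_mean = [pl[order] for pl in p_mean]
    return AncestryResult(
        k,
        table.individuals,
        q_mean,
        p_mean,
        model_ll,
        float(np.mean(alpha_trace)),
        seed,
    )


def _model_loglik(codes, observed, q, p) -> float:
    n, n_loci, _ = codes.shape
    total = 0.0
    for l in range(n_loci):
        pl = p[l]
        c = codes[:, l, :]
        safe = np.where(c >= 0, c, 0)
        mix = (q[:, None, :] * pl.T[safe]).sum(axis=2)  # (n, 2)
        mix = np.where(observed[:, l, :], mix, 1.0)
        total += np.log(np.maximum(mix, 1e-300)).sum()
    return float(total)


def _update_alpha(rng, alpha: float, q: np.ndarray, step: float = 0.25) -> float:
    """Metropolis update for the shared Dirichlet concentration (uniform
    prior on (0, 10])."""
    from scipy.special import gammaln as _gl

    prop = alpha + rng.normal(0.0, step)
    if prop <= 0 or prop > 10.0:
        return alpha
    n, k = q.shape

    def logp(a: float) -> float:
        return n * (_gl(k * a) - k * _gl(a)) + (a - 1.0) * np.log(
            np.maximum(q, 1e-300)
        ).sum()

    if np.log(rng.random()) < logp(prop) - logp(alpha):
        return prop
    return alpha


def _canonical_order(table, q_mean, anchor_ids) -> np.ndarray:
    if anchor_ids:
        idx = [i for i, ind in enumerate(table.individuals) if ind in set(anchor_ids)]
    else:
        idx = list(range(len(table.individuals)))
    anchor_q = q_mean[idx].mean(axis=0)
    return np.argsort(-anchor_q, kind="stable")


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KSelection:
    likelihood_table: pd.DataFrame  # index K: mean_lnL, sd_lnL, delta_k
    best_k_likelihood: int
    best_k_evanno: int | None


def select_k(runs: list[AncestryResult]) -> KSelection:
    """Rank K by mean model log-likelihood and by the Evanno delta-K.

    ``runs`` holds replicate runs across a contiguous K range; delta-K(K) =
    mean|L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) needs >= 3 consecutive K
    values and a nonzero replicate sd (flagged NaN otherwise).
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.k, []).append(r.log_likelihood)
    ks = sorted(by_k)
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) if len(by_k[k]) > 1 else 0.0 for k in ks}
    delta = {}
    for k in ks:
        if k - 1 in by_k and k + 1 in by_k:
            if sd[k] > 0:
                delta[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
            else:
                logger.warning("delta-K undefined at K=%d (replicate sd = 0)", k)
                delta[k] = np.nan
        else:
            delta[k] = np.nan
    df = pd.DataFrame(
        {
            "mean_lnL": [mean[k] for k in ks],
            "sd_lnL": [sd[k] for k in ks],
            "delta_k": [delta[k] for k in ks],
        },
        index=pd.Index(ks, name="K"),
    )
    best_ll = int(df["mean_lnL"].idxmax())
    finite = df["delta_k"].dropna()
    best_ev = int(finite.idxmax()) if len(finite) else None
    return KSelection(df, best_ll, best_ev)


def replicate_runs(
    table: GenotypeTable,
    k_range: range,
    n_replicates: int = 10,
    n_sweeps: int = 2_000,
    burnin: int = 500,
    seed: int = 0,
    alpha_mode: str = "fixed",
    anchor_ids: tuple[str, ...] | None = None,
) -> list[AncestryResult]:
    """Replicate admixture runs over a K range with derived seeds."""
    runs = []
    for k in k_range:
        for rep in range(n_replicates):
            runs.append(
                admixture_mcmc(
                    table,
                    k,
                    n_sweeps=n_sweeps,
                    burnin=burnin,
                    seed=(seed * 1_000_003 + k * 101 + rep) % (2**31 - 1),
                    alpha_mode=alpha_mode,
                    anchor_ids=anchor_ids,
                )
            )
    return runs
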