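"""The private-allele channel-hypothesis test.

Alleles observed in one distal "pure" reference site but not the other are
diagnostic of a side of the river.  If meander-loop cutoff transferred the
cis populations across the river, the *historical* (pre-cutoff) channel —
under which cis sites group with their control sites — should predict
where those private alleles are found better than the *current* channel,
under which cis sites group with trans sites.

The test filters private alleles to a diagnostic set (prevalence >= 15%
in their pure site of origin and >= 10% overall, one allele per locus,
thresholds inclusive), optionally adds the two mtDNA haplogroups as a
mirrored pair of pseudo-alleles, scores every site x allele group as
k-of-n individuals possessing the allele, and fits two binomial-logit
mixed models (fixed effect: native side under the chosen channel; crossed
random intercepts: latitude and allele group; maximum likelihood via the
Laplace approximation).  The hypotheses are compared by
dAIC = AIC(current) - AIC(historical): positive values favour the
historical channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from .assignment import HaplogroupAssignment
from .study_io import MISSING, GenotypeTable, SiteMetadata

logger = logging.getLogger(__name__)

MT_LOCUS = "cytb"
MT_WEST = "mtDNA-west"
MT_EAST = "mtDNA-east"


# ---------------------------------------------------------------------------
# private alleles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrivateAlleleRecord:
    locus: str
    allele: int | str
    origin: str  # "west" / "east"
    freq_pure: float
    freq_overall: float
    passed_prevalence: bool
    passed_overall: bool
    selected: bool = False
    group_id: str = ""


def find_private_alleles(
    table: GenotypeTable,
    west_pure: str,
    east_pure: str,
    prevalence_min: float = 0.15,
    overall_min: float = 0.10,
) -> list[PrivateAlleleRecord]:
    """Every allele observed in exactly one pure site, with its frequency
    there and in the whole dataset (deterministic locus/allele order)."""
    out: list[PrivateAlleleRecord] = []
    wmask = table.site_mask(west_pure)
    emask = table.site_mask(east_pure)
    if not wmask.any() or not emask.any():
        raise ValueError("both pure sites must be present")
    for l, locus in enumerate(table.loci):
        gw = table.alleles[wmask, l, :]
        ge = table.alleles[emask, l, :]
        gw = gw[gw[:, 0] != MISSING].ravel()
        ge = ge[ge[:, 0] != MISSING].ravel()
        if gw.size == 0 or ge.size == 0:
            logger.warning(
                "locus %s has no pure-site data on one side; skipped", locus
            )
            continue
        gall = table.alleles[:, l, :]
        gall = gall[gall[:, 0] != MISSING].ravel()
        set_w, set_e = set(gw.tolist()), set(ge.tolist())
        for origin, own, private in (
            ("west", gw, sorted(set_w - set_e)),
            ("east", ge, sorted(set_e - set_w)),
        ):
            for allele in private:
                fp = float((own == allele).mean())
                fo = float((gall == allele).mean())
                out.append(
                    PrivateAlleleRecord(
                        locus,
                        int(allele),
                        origin,
                        fp,
                        fo,
                        fp >= prevalence_min - 1e-12,
                        fo >= overall_min - 1e-12,
                        group_id=f"{locus}:{allele}",
                    )
                )
    out.sort(key=lambda r: (table.loci.index(r.locus), r.allele))
    return out


def filter_diagnostic(
    records: list[PrivateAlleleRecord],
    one_per_locus: bool = True,
) -> list[PrivateAlleleRecord]:
    """Diagnostic subset: prevalence filter, then overall-frequency filter,
    then at most one allele per locus (highest overall frequency wins,
    ties broken by the lower allele code)."""
    passing = [r for r in records if r.passed_prevalence and r.passed_overall]
    if one_per_locus:
        best: dict[str, PrivateAlleleRecord] = {}
        for r in passing:
            cur = best.get(r.locus)
            if (
                cur is None
                or r.freq_overall > cur.freq_overall + 1e-12
                or (
                    abs(r.freq_overall - cur.freq_overall) <= 1e-12
                    and r.allele < cur.allele
                )
            ):
                best[r.locus] = r
        passing = sorted(best.values(), key=lambda r: (r.locus, str(r.allele)))
    return [replace(r, selected=True) for r in passing]


def add_mtdna_pseudoalleles(
    assignments: list[HaplogroupAssignment],
    site_of: dict[str, str],
    west_pure: str,
    east_pure: str,
    shared_group: bool = True,
) -> list[PrivateAlleleRecord]:
    """Score the two mtDNA haplogroups as a mirrored pair of bi-allelic
    private pseudo-alleles.

    By default the two mirrored records share one allele-group id so they
    contribute a single level to the allele random effect."""
    assigned = [a for a in assignments if a.haplogroup != "unassigned"]
    if not assigned:
        raise ValueError("no assigned haplotypes to score")
    n_all = len(assigned)

    def frac(site: str, group: str) -> float:
        sub = [a for a in assigned if site_of[a.individual_id] == site]
        if not sub:
            return 0.0
        return float(np.mean([a.haplogroup == group for a in sub]))

    records = []
    for allele, origin, pure in ((MT_WEST, "west", west_pure), (MT_EAST, "east", east_pure)):
        fp = frac(pure, origin)
        fo = float(np.mean([a.haplogroup == origin for a in assigned]))
        gid = MT_LOCUS if shared_group else f"{MT_LOCUS}:{allele}"
        records.append(
            PrivateAlleleRecord(
                MT_LOCUS, allele, origin, fp, fo, True, True, True, gid
            )
        )
    return records


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelDesignRow:
    site_id: str
    group_id: str
    k: int
    n: int
    native_historical: int
    native_current: int
    latitude: str
    is_mtdna: bool = False


def build_design(
    selected: list[PrivateAlleleRecord],
    sites: list[SiteMetadata],
    table: GenotypeTable,
    assignments: list[HaplogroupAssignment] | None = None,
    include_pure: bool = True,
) -> list[ChannelDesignRow]:
    """One row per scored site x allele group: k carriers of n scored.

    ``native_historical`` uses ``bank_historical`` (cis grouped with
    control), ``native_current`` uses ``bank_current`` (cis grouped with
    trans).  k = 0 rows are retained — zeroes are data.
    """
    if not selected:
        raise ValueError("no selected alleles to score")
    site_list = [s for s in sites if include_pure or s.role != "pure"]
    hap_by_site: dict[str, list[HaplogroupAssignment]] = {}
    if assignments:
        ind_site = {}
        for ind, site in zip(table.individuals, table.site_of):
            ind_site[ind] = site
        for a in assignments:
            if a.haplogroup != "unassigned":
                hap_by_site.setdefault(ind_site[a.individual_id], []).append(a)
    rows = []
    for meta in site_list:
        mask = table.site_mask(meta.site_id)
        if not mask.any():
            continue
        block = table.alleles[mask]
        for rec in selected:
            if rec.locus == MT_LOCUS:
                subs = hap_by_site.get(meta.site_id, [])
                n = len(subs)
                k = sum(a.haplogroup == rec.origin for a in subs)
                is_mt = True
            else:
                l = table.loci.index(rec.locus)
                g = block[:, l, :]
                scored = g[:, 0] != MISSING
                n = int(scored.sum())
                k = int(((g == rec.allele).any(axis=1) & scored).sum())
                is_mt = False
            rows.append(
                ChannelDesignRow(
                    site_id=meta.site_id,
                    group_id=rec.group_id,
                    k=k,
                    n=n,
                    native_historical=int(meta.bank_historical == rec.origin),
                    native_current=int(meta.bank_current == rec.origin),
                    latitude=meta.latitude_group,
                    is_mtdna=is_mt,
                )
            )
    return rows


# ---------------------------------------------------------------------------
# binomial GLMM by Laplace approximation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelModelFit:
    channel: str
    intercept: float
    coefficient: float
    se: float
    z: float
    p_value: float
    odds_ratio: float
    odds_ratio_interval: tuple[float, float]  # +- one SE on the log-odds scale
    var_latitude: float
    var_allele: float
    log_likelihood: float
    aic: float
    flagged: str | None = None


def _design_arrays(rows: list[ChannelDesignRow], channel: str):
    if channel not in ("historical", "current"):
        raise ValueError("channel must be 'historical' or 'current'")
    k = np.array([r.k for r in rows], dtype=float)
    n = np.array([r.n for r in rows], dtype=float)
    x = np.array(
        [
            r.native_historical if channel == "historical" else r.native_current
            for r in rows
        ],
        dtype=float,
    )
    lats = sorted({r.latitude for r in rows})
    grps = sorted({r.group_id for r in rows})
    li = np.array([lats.index(r.latitude) for r in rows])
    gi = np.array([grps.index(r.group_id) for r in rows])
    return k, n, x, li, gi, len(lats), len(grps)


def _laplace_loglik(params, k, n, x, li, gi, nl, ng) -> float:
    """Marginal log-likelihood by Laplace approximation (joint mode over
    all crossed random intercepts)."""
    b0, b1, lsl, lsg = params
    sl2 = np.exp(2.0 * np.clip(lsl, -8.0, 4.0))
    sg2 = np.exp(2.0 * np.clip(lsg, -8.0, 4.0))
    q = nl + ng
    u = np.zeros(q)
    dinv = np.concatenate([np.full(nl, 1.0 / sl2), np.full(ng, 1.0 / sg2)])
    Z_l, Z_g = li, nl + gi
    const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    def eta(u):
        return b0 + b1 * x + u[Z_l] + u[Z_g]

    for _ in range(100):
        e = eta(u)
        p = expit(e)
        w = n * p * (1.0 - p)
        resid = k - n * p
        grad = np.zeros(q)
        np.add.at(grad, Z_l, resid)
        np.add.at(grad, Z_g, resid)
        grad -= dinv * u
        H = np.zeros((q, q))
        for a, b in ((Z_l, Z_l), (Z_l, Z_g), (Z_g, Z_l), (Z_g, Z_g)):
            np.add.at(H, (a, b), w)
        H[np.diag_indices(q)] += dinv
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return -1e10
        u_new = u + step
        if np.max(np.abs(step)) < 1e-10:
            u = u_new
            break
        u = u_new
    e = eta(u)
    p = expit(e)
    w = n * p * (1.0 - p)
    H = np.zeros((q, q))
    for a, b in ((Z_l, Z_l), (Z_l, Z_g), (Z_g, Z_l), (Z_g, Z_g)):
        np.add.at(H, (a, b), w)
    H[np.diag_indices(q)] += dinv
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -1e10
    joint = (
        (const + k * e - n * np.logaddexp(0.0, e)).sum()
        - 0.5 * (dinv * u**2).sum()
        - 0.5 * nl * np.log(2 * np.pi * sl2)
        - 0.5 * ng * np.log(2 * np.pi * sg2)
    )
    return float(joint + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet)


def fit_mixed_logit(
    rows: list[ChannelDesignRow],
    channel: str,
    n_restarts: int = 3,
) -> ChannelModelFit:
    """ML fit of the binomial-logit mixed model for one channel hypothesis.

    Fixed effects: intercept and the native flag under ``channel``; crossed
    random intercepts for latitude and allele group; AIC counts 4
    parameters (b0, b1, two variances).  Complete separation or a runaway
    coefficient is flagged, not silently returned.
    """
    k, n, x, li, gi, nl, ng = _design_arrays(rows, channel)
    if nl < 2 or ng < 2:
        raise ValueError("need >= 2 levels for each random effect")
    if len(set(x)) < 2:
        raise ValueError("both native and non-native rows are required")

    def negll(params):
        return -_laplace_loglik(params, k, n, x, li, gi, nl, ng)

    p_overall = k.sum() / n.sum()
    base = float(np.log(p_overall / (1 - p_overall)))
    starts = [
        np.array([base, 0.0, -1.0, -1.0]),
        np.array([base, 0.5, 0.0, 0.0]),
        np.array([base, -0.5, -2.0, -0.5]),
    ][:n_restarts]
    best = None
    for s in starts:
        res = minimize(negll, s, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("mixed-logit fit did not converge")
    b0, b1, lsl, lsg = best.x
    lnl = -best.fun

    # SE of the native coefficient from the profile curvature
    h = 1e-4
    def ll_b1(v):
        return _laplace_loglik([b0, v, lsl, lsg], k, n, x, li, gi, nl, ng)
    d2 = (ll_b1(b1 + h) - 2.0 * lnl + ll_b1(b1 - h)) / h**2
    se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.inf

    flagged = None
    lev = [k[x == v].sum() / n[x == v].sum() for v in (0.0, 1.0)]
    if any(np.isclose(p, 0.0) or np.isclose(p, 1.0) for p in lev):
        flagged = "separation: a predictor level is all-0 or all-n"
        logger.warning("fit_mixed_logit(%s): %s", channel, flagged)
    elif abs(b1) > 10:
        flagged = "runaway coefficient"
        logger.warning("fit_mixed_logit(%s): %s", channel, flagged)

    from scipy.stats import norm

    z = b1 / se if np.isfinite(se) and se > 0 else np.nan
    return ChannelModelFit(
        channel=channel,
        intercept=float(b0),
        coefficient=float(b1),
        se=se,
        z=float(z),
        p_value=float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        odds_ratio=float(np.exp(b1)),
        odds_ratio_interval=(float(np.exp(b1 - se)), float(np.exp(b1 + se))),
        var_latitude=float(np.exp(2 * lsl)),
        var_allele=float(np.exp(2 * lsg)),
        log_likelihood=float(lnl),
        aic=float(-2 * lnl + 2 * 4),
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# hypothesis comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelComparison:
    fit_historical: ChannelModelFit
    fit_current: ChannelModelFit
    delta_aic: float  # AIC(current) - AIC(historical); > 0 favours historical
    preferred: str
    msats_only: "ChannelComparison | None" = None


def compare_channels(
    rows: list[ChannelDesignRow], with_msat_branch: bool = True
) -> ChannelComparison:
    """Fit both channel hypotheses and compare by AIC.

    When the two designs are identical (no cis sites), one fit is reused
    for both and dAIC is exactly 0.  When mtDNA pseudo-allele rows are
    present the microsatellite-only branch is also computed.
    """
    identical = all(r.native_historical == r.native_current for r in rows)
    fit_h = fit_mixed_logit(rows, "historical")
    if identical:
        fit_c = replace(fit_h, channel="current")
    else:
        fit_c = fit_mixed_logit(rows, "current")
    delta = fit_c.aic - fit_h.aic
    msat_rows = [r for r in rows if not r.is_mtdna]
    msats_only = None
    if (
        with_msat_branch
        and len(msat_rows) < len(rows)
        and len({r.group_id for r in msat_rows}) >= 2
    ):
        msats_only = compare_channels(msat_rows)
    return ChannelComparison(
        fit_historical=fit_h,
        fit_current=fit_c,
        delta_aic=float(delta),
        preferred="historical" if delta > 0 else "current",
        msats_only=msats_only,
    )


def summarize_proportions(rows: list[ChannelDesignRow]) -> "object":
    """Mean carrier proportion by native/non-native under each channel
    (with binomial standard errors), per data branch — the summary behind
    the usual two-panel figure."""
    import pandas as pd

    recs = []
    for branch, sel in (
        ("combined", rows),
        ("msats_only", [r for r in rows if not r.is_mtdna]),
    ):
        if not sel:
            continue
        for channel in ("historical", "current"):
            for native in (1, 0):
                grp = [
                    r
                    for r in sel
                    if (
                        r.native_historical
                        if channel == "historical"
                        else r.native_current
                    )
                    == native
                ]
                if not grp:
                    continue
                props = [r.k / r.n for r in grp if r.n > 0]
                recs.append(
                    {
                        "branch": branch,
                        "channel": channel,
                        "native": bool(native),
                        "mean_proportion": float(np.mean(props)),
                        "se": float(np.std(props, ddof=1) / np.sqrt(len(props)))
                        if len(props) > 1
                        else np.nan,
                        "n_rows": len(grp),
                    }
                )
    return pd.DataFrame(recs)
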