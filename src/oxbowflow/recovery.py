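"""Mechanism-recovery and null-calibration harness.

Runs the scaled-down end-to-end experiment used to validate the pipeline:
simulate a three-oxbow study with a recent cutoff (or its no-cutoff null,
in which every site is drawn from one panmictic pool and the role labels
are arbitrary), run the relevant inference stages, and score the four
headline direction tests:

* P1 — D_est(cis, control) < D_est(cis, trans);
* P2 — non-native admixture ancestry higher at cis than at its control;
* P3 — posterior immigration control -> cis exceeds cis -> control
  (averaged over the three latitudes and replicate chains, the study-level
  form of the claim);
* P6 — dAIC favours the historical channel.

P1 and P2 are scored at the northern oxbow, the oldest and (as in the
field system) the one with the most consistent signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import channel_test as ct
from . import migration as mig
from .assignment import admixture_mcmc, assign_haplogroups
from .popgen_stats import d_est_jost
from .study_io import StudyDataset
from .synthetic_data import SimulationConfig, simulate_study

#: latitude used for the single-latitude direction tests
FOCAL_LATITUDE = "north"


def mechanism_config(seed: int) -> SimulationConfig:
    """Three oxbows with a recent cutoff (20 generations, 10 isolated)."""
    return SimulationConfig(
        demes_per_bank=5,
        loop_positions=(1, 2, 3),
        t_cutoff=20,
        t_iso=10,
        sample_sizes={"cis": 25, "trans": 25, "control": 25, "pure": 15},
        seed=seed,
    )


def null_config(seed: int) -> SimulationConfig:
    """Same sampling layout, no bank split and no transfer event."""
    cfg = mechanism_config(seed)
    from dataclasses import replace

    return replace(cfg, t_split=0, t_cutoff=None, t_iso=0)


@dataclass(frozen=True)
class DirectionResults:
    """Point evidence and boolean verdicts for one simulated study."""

    d_cis_control: float
    d_cis_trans: float
    nonnative_cis: float
    nonnative_control: float
    m_asymmetry: float  # mean over latitudes of m[cis][ctl] - m[ctl][cis]
    delta_aic: float
    or_historical: float
    or_current: float

    @property
    def p1(self) -> bool:
        return self.d_cis_control < self.d_cis_trans

    @property
    def p2(self) -> bool:
        return self.nonnative_cis > self.nonnative_control

    @property
    def p3(self) -> bool:
        return self.m_asymmetry > 0

    @property
    def p6(self) -> bool:
        return self.delta_aic > 0


def direction_tests(
    dataset: StudyDataset,
    seed: int,
    cluster_sweeps: int = 600,
    cluster_burnin: int = 200,
    migration_samples: int = 800,
    migration_burnin: int = 800,
    migration_chains: int = 2,
) -> DirectionResults:
    """Compute the four direction statistics for one study."""
    table = dataset.genotypes
    site_of = dict(zip(table.individuals, table.site_of))
    west_pure = dataset.pure_site("west").site_id
    east_pure = dataset.pure_site("east").site_id
    trip = {lat: dataset.triplet(lat) for lat in dataset.latitudes}
    focal = trip[FOCAL_LATITUDE]
    cis = focal["cis"].site_id
    trans = focal["trans"].site_id
    control = focal["control"].site_id

    # P1 at the focal latitude
    _, d_cc, _ = d_est_jost(table, cis, control)
    _, d_ct, _ = d_est_jost(table, cis, trans)

    # P2: K=2 admixture over the focal triplet plus the pure anchors;
    # cluster 1 is canonically the west-anchored cluster
    anchor = tuple(i for i in table.individuals if site_of[i] == west_pure)
    sub = table.for_sites([cis, trans, control, west_pure, east_pure])
    run = admixture_mcmc(
        sub,
        2,
        n_sweeps=cluster_sweeps,
        burnin=cluster_burnin,
        seed=(seed * 7_919 + 1) % (2**31 - 1),
        anchor_ids=anchor,
    )
    means = run.site_means(site_of)
    cis_bank = focal["cis"].bank_current
    ctl_bank = focal["control"].bank_current
    nn_cis = float(
        means.loc[cis, "cluster_1" if cis_bank == "east" else "cluster_2"]
    )
    nn_ctl = float(
        means.loc[control, "cluster_1" if ctl_bank == "east" else "cluster_2"]
    )

    # P3: mean immigration asymmetry over latitudes, chains averaged
    asym = []
    for j, lat in enumerate(dataset.latitudes):
        t = trip[lat]
        sites = (
            t["cis"].site_id,
            t["trans"].site_id,
            t["control"].site_id,
            west_pure,
            east_pure,
        )
        est, _, _ = mig.mean_migration_over_chains(
            table,
            sites,
            n_chains=migration_chains,
            seed=(seed * 6_553 + j) % (2**31 - 1),
            n_samples=migration_samples,
            burnin=migration_burnin,
            thin=2,
        )
        asym.append(
            est.rate(sites[0], sites[2]) - est.rate(sites[2], sites[0])
        )

    # P6: channel comparison over all sites (combined branch only).  A
    # study can lack a usable diagnostic set (e.g. the exchangeable null,
    # where private alleles are sampling accidents); the comparison is
    # then undefined, not a verdict.
    recs = ct.find_private_alleles(table, west_pure, east_pure)
    sel = ct.filter_diagnostic(recs)
    wrefs = dataset.haplotypes.subset(anchor)
    erefs = dataset.haplotypes.subset(
        [i for i in table.individuals if site_of[i] == east_pure]
    )
    assignments = assign_haplogroups(dataset.haplotypes, wrefs, erefs)
    try:
        mt_records = ct.add_mtdna_pseudoalleles(
            assignments, site_of, west_pure, east_pure
        )
    except ValueError:
        mt_records = []
    try:
        rows = ct.build_design(
            sel + mt_records,
            list(dataset.analysis_sites),
            table,
            assignments=assignments,
        )
        cmpn = ct.compare_channels(rows, with_msat_branch=False)
        delta, or_h, or_c = (
            cmpn.delta_aic,
            cmpn.fit_historical.odds_ratio,
            cmpn.fit_current.odds_ratio,
        )
    except (ValueError, RuntimeError):
        delta = or_h = or_c = float("nan")

    return DirectionResults(
        d_cis_control=float(d_cc),
        d_cis_trans=float(d_ct),
        nonnative_cis=nn_cis,
        nonnative_control=nn_ctl,
        m_asymmetry=float(np.mean(asym)),
        delta_aic=float(delta),
        or_historical=float(or_h),
        or_current=float(or_c),
    )


def run_direction_suite(
    n_seeds: int, null: bool, base_seed: int = 0, **kwargs
) -> list[DirectionResults]:
    """Direction tests over ``n_seeds`` independent simulated studies."""
    out = []
    for k in range(n_seeds):
        seed = (base_seed * 100_003 + k) % (2**31 - 1)
        cfg = null_config(seed) if null else mechanism_config(seed)
        dataset, _ = simulate_study(cfg)
        out.append(direction_tests(dataset, seed=seed, **kwargs))
    return out


def wilson_interval(successes: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Wilson score 95% interval for a binomial proportion."""
    if n == 0:
        return 0.0, 1.0
    p = successes / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return float(centre - half), float(centre + half)
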