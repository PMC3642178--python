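"""Simulator invariants: determinism, conservation, role geometry and
population-genetic limits."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from oxbowflow.popgen_stats import d_est_jost, pairwise_fst
from oxbowflow.synthetic_data import (
    ConfigError,
    SimulationConfig,
    make_fixture,
    simulate_study,
    truth_migration_matrix,
)


class TestConfigValidation:
    def test_rejects_bad_rates_and_times(self):
        with pytest.raises(ConfigError):
            SimulationConfig(m_along=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(t_cutoff=600, t_split=500)
        with pytest.raises(ConfigError):
            SimulationConfig(t_iso=30, t_cutoff=20)
        with pytest.raises(ConfigError):
            SimulationConfig(loop_positions=(9,), demes_per_bank=3)
        with pytest.raises(ConfigError):
            SimulationConfig(m_along=0.4, m_loop=0.4)


class TestSimulation:
    def test_identical_seeds_reproduce_identical_studies(self):
        a, _ = simulate_study(SimulationConfig(seed=11, t_split=60))
        b, _ = simulate_study(SimulationConfig(seed=11, t_split=60))
        assert a.genotypes.equals(b.genotypes)
        assert np.array_equal(a.haplotypes.seqs, b.haplotypes.seqs)

    def test_sampled_totals_match_configuration(self, default_study):
        dataset, truth = default_study
        cfg = truth.config
        for meta in dataset.analysis_sites:
            expect = cfg.sample_overrides.get(
                meta.site_id, cfg.sample_sizes[meta.role]
            )
            assert dataset.genotypes.site_size(meta.site_id) == expect

    def test_no_divergence_limit_has_near_zero_cross_bank_fst(self):
        cfg = SimulationConfig(
            deme_size=100,
            t_split=0,
            t_cutoff=None,
            t_iso=0,
            sample_sizes={"cis": 20, "trans": 20, "control": 20, "pure": 20},
            seed=2,
        )
        ds, truth = simulate_study(cfg)
        assert not truth.transferred
        theta = pairwise_fst(ds.genotypes, "west_pure", "east_pure")[1]
        assert abs(theta) < 0.02

    def test_complete_isolation_sorts_haplogroups_by_bank(self):
        cfg = SimulationConfig(t_cutoff=None, t_iso=0, t_split=400, seed=4)
        ds, truth = simulate_study(cfg)
        # with no cutoff and m_cross=0 every mtDNA variant is bank-private:
        # pure-site sequence sets must be disjoint
        site_of = dict(zip(ds.genotypes.individuals, ds.genotypes.site_of))
        west = {
            ds.haplotypes.sequence(i)
            for i in ds.haplotypes.ids
            if site_of[i] == "west_pure"
        }
        east = {
            ds.haplotypes.sequence(i)
            for i in ds.haplotypes.ids
            if site_of[i] == "east_pure"
        }
        assert not west & east

    def test_recent_cutoff_leaves_cis_closest_to_control(self):
        wins = 0
        for seed in range(10):
            ds, _ = simulate_study(SimulationConfig(seed=100 + seed))
            d_cc = d_est_jost(ds.genotypes, "north_cis", "north_control")[1]
            d_ct = d_est_jost(ds.genotypes, "north_cis", "north_trans")[1]
            wins += d_cc < d_ct
        assert wins >= 8

    def test_cross_bank_fst_increases_with_split_time(self):
        # low mutation keeps homoplasy from saturating theta inside the
        # tested range
        pts = []
        for t_split in (50, 150, 300, 500):
            for seed in range(5):
                cfg = SimulationConfig(
                    deme_size=60,
                    demes_per_bank=1,
                    loop_positions=(),
                    t_split=t_split,
                    t_cutoff=None,
                    t_iso=0,
                    msat_mut_rate=1e-3,
                    sample_sizes={"pure": 20},
                    seed=seed,
                )
                ds, _ = simulate_study(cfg)
                pts.append(
                    (t_split, pairwise_fst(ds.genotypes, "west_pure", "east_pure")[1])
                )
        arr = np.asarray(pts)
        assert spearmanr(arr[:, 0], arr[:, 1]).statistic > 0.9


class TestFixtures:
    def test_tiny_fixture_shape(self, tiny_study):
        dataset, truth = tiny_study
        assert dataset.genotypes.n_individuals == 16
        assert dataset.genotypes.n_loci == 3
        assert len(dataset.analysis_sites) == 2

    def test_paper_shape_counts(self, paper_shape_study):
        dataset, _ = paper_shape_study
        assert dataset.genotypes.n_individuals == 260
        assert len(dataset.sites) == 15
        assert len(dataset.analysis_sites) == 11
        assert dataset.genotypes.n_loci == 13
        assert dataset.haplotypes.alignment_length == 809

    def test_null_fixture_records_no_transfer(self, null_study):
        _, truth = null_study
        assert not truth.transferred
        assert truth.transferred_demes == {}

    def test_unknown_fixture_lists_options(self):
        with pytest.raises(ValueError, match="tiny"):
            make_fixture("nope")


class TestTruthMatrix:
    def test_rows_are_stochastic_and_cross_bank_zero(self, default_study):
        _, truth = default_study
        m = truth_migration_matrix(truth, 50)
        assert np.allclose(m.sum(axis=1), 1.0)
        names = truth.deme_names
        banks = truth.deme_bank_precutoff
        # m_cross = 0: a bank deme never draws parents from the other bank
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if {a[0], b[0]} == {"W", "E"}:
                    assert m[i, j] == 0.0

    def test_cutoff_window_shows_pure_loop_ancestry(self, default_study):
        _, truth = default_study
        cfg = truth.config
        # window covering only the isolation phase: the cis deme draws all
        # parents from itself (its pre-cutoff, west-bank stock)
        window = cfg.cutoffs[0] - cfg.isolations[0]
        m = truth_migration_matrix(truth, cfg.cutoffs[0])[
            truth.deme_names.index("C0")
        ]
        iso_m = truth.parent_counts[
            cfg.t_split - cfg.cutoffs[0] : cfg.t_split - cfg.cutoffs[0] + cfg.isolations[0],
            truth.deme_names.index("C0"),
        ].sum(axis=0)
        assert iso_m[truth.deme_names.index("C0")] == iso_m.sum()

    def test_symmetric_migration_is_symmetric_up_to_noise(self):
        cfg = SimulationConfig(
            demes_per_bank=2,
            loop_positions=(),
            t_split=400,
            t_cutoff=None,
            t_iso=0,
            seed=9,
        )
        _, truth = simulate_study(cfg)
        m = truth_migration_matrix(truth, 400)
        i, j = truth.deme_names.index("W0"), truth.deme_names.index("W1")
        # both entries estimate m_along = 0.02 from ~ 400*2N draws
        se = 3 * np.sqrt(0.02 / (400 * 2 * cfg.deme_size))
        assert abs(m[i, j] - m[j, i]) < 2 * se + 0.005

    def test_bad_window_is_an_error(self, default_study):
        _, truth = default_study
        with pytest.raises(ValueError):
            truth_migration_matrix(truth, 0)
        with pytest.raises(ValueError):
            truth_migration_matrix(truth, 10_000)
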