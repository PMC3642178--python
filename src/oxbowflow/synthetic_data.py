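"""Forward-time simulator of a two-bank metapopulation with meander-loop
cutoff (MLC) transfer events.

The model is a discrete-generation Wright–Fisher metapopulation.  A single
ancestral deme is run to build standing microsatellite variation, then two
river banks of ``demes_per_bank`` demes each are founded and evolve with
stepping-stone migration along each bank (``m_along`` per neighbour per
generation) and optional across-river leakage between facing demes
(``m_cross``, default 0 — the river is a hard barrier).

Each simulated oxbow is an extra "loop" deme attached to a host deme on
the west bank.  ``t_cutoff`` generations before present the loop is severed
and transferred to the east bank: it exchanges no migrants for ``t_iso``
generations (the receding oxbow) and thereafter exchanges only with its new
east-bank neighbour.  Sampling maps demes to field roles: the transferred
loop deme is the *cis* site; its old host across the new channel is the
*control*; its new same-bank neighbour is the *trans* site; the distal deme
on each bank is a *pure* reference site.

Markers mirror the field data: unlinked microsatellites under a strict
single-step mutation model with reflecting bounds (keeps allele codes
3-digit safe), and a maternally inherited, non-recombining mtDNA locus with
per-site mutation.  mtDNA is monomorphic at the bank split, so the two
bank haplogroups are reciprocally monophyletic by construction and their
expected divergence is ``2 * t_split * mtdna_mut_rate`` — the defaults give
the ~6% uncorrected distance characteristic of deeply divergent riverine
haplogroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .study_io import (
    GenotypeTable,
    HaplotypeSet,
    SiteMetadata,
    StudyDataset,
)

_LATITUDE_NAMES = ("north", "central", "south")
_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any simulation)."""


def _per_loop(value, n: int, name: str) -> tuple:
    """Broadcast a scalar or per-loop sequence to one value per loop."""
    if value is None or isinstance(value, (int, float)):
        return tuple([value] * n)
    value = tuple(value)
    if len(value) != n:
        raise ConfigError(f"{name} must be scalar or length {n}")
    return value


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters of one simulated study.

    Defaults describe a single recent oxbow on a deeply split river system:
    a cutoff 20 generations ago followed by 10 generations of oxbow
    isolation, on banks separated for 300 generations.
    """

    deme_size: int = 100
    demes_per_bank: int = 3
    t_split: int = 500
    t_cutoff: int | Sequence[int] | None = 20
    t_iso: int | Sequence[int] = 10
    m_along: float = 0.02
    m_cross: float = 0.0
    m_loop: float = 0.3
    n_msat_loci: int = 13
    msat_mut_rate: float = 0.008
    msat_bounds: tuple[int, int] = (5, 60)
    mtdna_length: int = 809
    mtdna_mut_rate: float = 6.0e-5
    loop_positions: tuple[int, ...] = (1,)
    sample_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"cis": 25, "trans": 25, "control": 25, "pure": 15}
    )
    sample_overrides: Mapping[str, int] = field(default_factory=dict)
    n_ancestral: int = 200
    ancestral_burnin: int = 60
    init_allele_sd: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.deme_size < 2 or self.n_ancestral < 2:
            raise ConfigError("deme sizes must be >= 2")
        if self.demes_per_bank < 1:
            raise ConfigError("need at least one deme per bank")
        for r in (
            self.m_along,
            self.m_cross,
            self.m_loop,
            self.msat_mut_rate,
            self.mtdna_mut_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if self.t_split < 0:
            raise ConfigError("t_split must be >= 0")
        n_loops = len(self.loop_positions)
        for p in self.loop_positions:
            if not 0 <= p < self.demes_per_bank:
                raise ConfigError(f"loop position {p} outside bank")
        if n_loops > len(_LATITUDE_NAMES):
            raise ConfigError("at most three oxbow loops are supported")
        for tc, ti in zip(self.cutoffs, self.isolations):
            if tc is not None:
                if not 0 < tc < max(self.t_split, 1):
                    raise ConfigError("need 0 < t_cutoff < t_split")
                if ti is None or ti < 0 or ti > tc:
                    raise ConfigError("need 0 <= t_iso <= t_cutoff")
        # backward migration out of any deme must leave room for self
        worst = max(
            2 * self.m_along + self.m_loop + self.m_cross,
            3 * self.m_along + self.m_cross,
        )
        if worst >= 1.0:
            raise ConfigError("migration fractions out of a deme must sum < 1")

    @property
    def cutoffs(self) -> tuple:
        return _per_loop(self.t_cutoff, len(self.loop_positions), "t_cutoff")

    @property
    def isolations(self) -> tuple:
        return _per_loop(self.t_iso, len(self.loop_positions), "t_iso")

    @property
    def latitudes(self) -> tuple[str, ...]:
        return _LATITUDE_NAMES[: len(self.loop_positions)]


@dataclass(eq=False)
class SimulationTruth:
    """Ground truth behind one simulated study.

    ``parent_counts[t, d, s]`` counts parent lineages drawn by deme ``d``
    from deme ``s`` in post-split generation ``t`` (two per offspring).
    """

    config: SimulationConfig
    deme_names: tuple[str, ...]
    deme_bank_current: tuple[str, ...]
    deme_bank_precutoff: tuple[str, ...]
    transferred_demes: dict[str, str]  # latitude -> deme name; empty if none
    individual_deme: dict[str, str]
    parent_counts: np.ndarray

    @property
    def transferred(self) -> bool:
        return bool(self.transferred_demes)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class _Engine:
    """Vectorised Wright–Fisher reproduction over a set of demes."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.hap_store: list[np.ndarray] = [
            rng.integers(0, 4, size=config.mtdna_length).astype(np.uint8)
        ]

    def init_pool(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.cfg
        lo, hi = cfg.msat_bounds
        centre = (lo + hi) / 2
        geno = np.rint(
            self.rng.normal(centre, cfg.init_allele_sd, size=(1, n, cfg.n_msat_loci, 2))
        ).astype(np.int16)
        np.clip(geno, lo, hi, out=geno)
        mt = np.zeros((1, n), dtype=np.int32)
        return geno, mt

    def _mutate_msat(self, geno: np.ndarray) -> None:
        cfg = self.cfg
        mask = self.rng.random(geno.shape) < cfg.msat_mut_rate
        k = int(mask.sum())
        if not k:
            return
        steps = self.rng.integers(0, 2, size=k).astype(np.int16) * 2 - 1
        vals = geno[mask] + steps
        lo, hi = cfg.msat_bounds
        vals[vals > hi] = hi - 1
        vals[vals < lo] = lo + 1
        geno[mask] = vals

    def _mutate_mt(self, mt: np.ndarray) -> None:
        cfg = self.cfg
        if cfg.mtdna_mut_rate <= 0:
            return
        n_mut = self.rng.binomial(cfg.mtdna_length, cfg.mtdna_mut_rate, size=mt.shape)
        for d, i in zip(*np.nonzero(n_mut)):
            seq = self.hap_store[mt[d, i]].copy()
            pos = self.rng.choice(cfg.mtdna_length, size=n_mut[d, i], replace=False)
            seq[pos] = (seq[pos] + self.rng.integers(1, 4, size=len(pos))) % 4
            self.hap_store.append(seq)
            mt[d, i] = len(self.hap_store) - 1

    def step(
        self,
        geno: np.ndarray,
        mt: np.ndarray,
        mig: np.ndarray,
        counts_out: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """One synchronous generation for all demes (constant deme size)."""
        rng = self.rng
        n_demes, n, n_loci, _ = geno.shape
        src = np.empty((n_demes, n, 2), dtype=np.intp)
        for d in range(n_demes):
            row = mig[d]
            if row[d] >= 1.0:
                src[d] = d
            else:
                src[d] = rng.choice(n_demes, size=(n, 2), p=row)
        pidx = rng.integers(0, n, size=(n_demes, n, 2))
        choice = rng.integers(0, 2, size=(n_demes, n, 2, n_loci))
        l_idx = np.arange(n_loci)[None, None, None, :]
        gam = geno[src[..., None], pidx[..., None], l_idx, choice]
        new_geno = np.ascontiguousarray(gam.transpose(0, 1, 3, 2))
        new_mt = mt[src[..., 0], pidx[..., 0]]
        if counts_out is not None:
            for d in range(n_demes):
                counts_out[d] += np.bincount(src[d].ravel(), minlength=n_demes)
        self._mutate_msat(new_geno)
        self._mutate_mt(new_mt)
        return new_geno, new_mt

    def found_demes(
        self, anc_geno: np.ndarray, anc_mt: np.ndarray, n_demes: int, n: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Found ``n_demes`` demes of size ``n`` from the ancestral pool."""
        rng = self.rng
        cfg = self.cfg
        n_anc = anc_geno.shape[1]
        pidx = rng.integers(0, n_anc, size=(n_demes, n, 2))
        choice = rng.integers(0, 2, size=(n_demes, n, 2, cfg.n_msat_loci))
        l_idx = np.arange(cfg.n_msat_loci)[None, None, None, :]
        gam = anc_geno[0][pidx[..., None], l_idx, choice]
        geno = np.ascontiguousarray(gam.transpose(0, 1, 3, 2))
        mt = anc_mt[0][pidx[..., 0]]
        self._mutate_msat(geno)
        self._mutate_mt(mt)
        return geno, mt

    def haplotype_bytes(self, hap_ids: np.ndarray) -> np.ndarray:
        """Decode stored haplotype ids to an (n, L) ASCII base array."""
        return _ACGT[np.stack([self.hap_store[h] for h in hap_ids])]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Deme:
    name: str
    bank: str  # founding bank
    position: int
    kind: str  # "bank" or "loop"
    loop_index: int = -1


def _build_demes(cfg: SimulationConfig) -> list[_Deme]:
    L = cfg.demes_per_bank
    demes = [_Deme(f"W{p}", "west", p, "bank") for p in range(L)]
    demes += [_Deme(f"E{p}", "east", p, "bank") for p in range(L)]
    for j, p in enumerate(cfg.loop_positions):
        demes.append(_Deme(f"C{j}", "west", p, "loop", loop_index=j))
    return demes


def _loop_state(cfg: SimulationConfig, j: int, t: int) -> str:
    """State of loop j at post-split generation t: west / iso / east."""
    tc = cfg.cutoffs[j]
    if tc is None:
        return "west"
    cut_gen = cfg.t_split - tc
    if t < cut_gen:
        return "west"
    if t < cut_gen + cfg.isolations[j]:
        return "iso"
    return "east"


def _migration_matrix(cfg: SimulationConfig, demes: list[_Deme], t: int) -> np.ndarray:
    """Backward migration matrix (row d = parental source fractions)."""
    L = cfg.demes_per_bank
    n = len(demes)
    index = {d.name: i for i, d in enumerate(demes)}
    mat = np.zeros((n, n))

    def link(a: str, b: str, m: float) -> None:
        if m > 0:
            mat[index[a], index[b]] += m
            mat[index[b], index[a]] += m

    for bank, pref in (("west", "W"), ("east", "E")):
        for p in range(L - 1):
            link(f"{pref}{p}", f"{pref}{p + 1}", cfg.m_along)
    for p in range(L):
        link(f"W{p}", f"E{p}", cfg.m_cross)
    for j, p in enumerate(cfg.loop_positions):
        state = _loop_state(cfg, j, t)
        if state == "west":
            # pre-cutoff the loop is contiguous habitat on its host bank
            link(f"C{j}", f"W{p}", cfg.m_loop)
        elif state == "east":
            # post-recession contact with the new bank is a narrow passage
            link(f"C{j}", f"E{p}", cfg.m_along)
        # iso: no links at all
    for i in range(n):
        off = mat[i].sum()
        if off >= 1.0:
            raise ConfigError("migration out of a deme sums to >= 1")
        mat[i, i] = 1.0 - off
    return mat


def _sampling_plan(cfg: SimulationConfig, demes: list[_Deme]) -> list[tuple[str, SiteMetadata, int, int]]:
    """(site_id, metadata, deme index, n) for every sampled site."""
    index = {d.name: i for i, d in enumerate(demes)}
    L = cfg.demes_per_bank
    plan: list[tuple[str, SiteMetadata, int, int]] = []

    def n_for(site_id: str, role: str) -> int:
        if site_id in cfg.sample_overrides:
            return int(cfg.sample_overrides[site_id])
        return int(cfg.sample_sizes[role])

    for j, lat in enumerate(cfg.latitudes):
        p = cfg.loop_positions[j]
        cis_id, trans_id, ctl_id = f"{lat}_cis", f"{lat}_trans", f"{lat}_control"
        plan.append(
            (
                cis_id,
                SiteMetadata(cis_id, "cis", lat, "east", "west", oxbow_id=lat),
                index[f"C{j}"],
                n_for(cis_id, "cis"),
            )
        )
        plan.append(
            (
                trans_id,
                SiteMetadata(trans_id, "trans", lat, "east", "east", oxbow_id=lat),
                index[f"E{p}"],
                n_for(trans_id, "trans"),
            )
        )
        plan.append(
            (
                ctl_id,
                SiteMetadata(ctl_id, "control", lat, "west", "west", oxbow_id=lat),
                index[f"W{p}"],
                n_for(ctl_id, "control"),
            )
        )
    plan.append(
        (
            "west_pure",
            SiteMetadata("west_pure", "pure", "none", "west", "west"),
            index["W0"],
            n_for("west_pure", "pure"),
        )
    )
    plan.append(
        (
            "east_pure",
            SiteMetadata("east_pure", "pure", "none", "east", "east"),
            index[f"E{L - 1}"],
            n_for("east_pure", "pure"),
        )
    )
    return plan


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig) -> tuple[StudyDataset, SimulationTruth]:
    """Run the forward simulation and emit a sampled study plus its truth.

    Identical configs (including seed) reproduce byte-identical output.
    With ``t_split == 0`` every site is sampled directly from the common
    ancestral pool (the no-divergence limit); with ``t_cutoff=None`` loop
    demes stay attached to their west-bank hosts and no transfer occurs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    eng = _Engine(cfg, rng)
    demes = _build_demes(cfg)
    n_demes = len(demes)

    anc_geno, anc_mt = eng.init_pool(cfg.n_ancestral)
    identity = np.eye(1)
    for _ in range(cfg.ancestral_burnin):
        anc_geno, anc_mt = eng.step(anc_geno, anc_mt, identity)

    counts = np.zeros((max(cfg.t_split, 1), n_demes, n_demes), dtype=np.int64)
    if cfg.t_split > 0:
        geno, mt = eng.found_demes(anc_geno, anc_mt, n_demes, cfg.deme_size)
        # segment the run by migration-matrix change points
        change_gens = {0, }
        for j in range(len(cfg.loop_positions)):
            tc = cfg.cutoffs[j]
            if tc is not None:
                change_gens.add(cfg.t_split - tc)
                change_gens.add(cfg.t_split - tc + cfg.isolations[j])
        mats = {t: _migration_matrix(cfg, demes, t) for t in change_gens}
        current = mats[0]
        for t in range(cfg.t_split):
            if t in mats:
                current = mats[t]
            geno, mt = eng.step(geno, mt, current, counts_out=counts[t])
    else:
        # no-divergence limit: each "deme" is a fresh offspring draw from
        # the one panmictic pool
        geno, mt = eng.found_demes(anc_geno, anc_mt, n_demes, cfg.deme_size)

    plan = _sampling_plan(cfg, demes)
    individuals: list[str] = []
    site_of: list[str] = []
    allele_rows: list[np.ndarray] = []
    hap_ids: list[str] = []
    hap_rows: list[np.ndarray] = []
    individual_deme: dict[str, str] = {}
    metas: list[SiteMetadata] = []
    for site_id, meta, deme_idx, n in plan:
        if n > cfg.deme_size:
            raise ConfigError(
                f"site {site_id}: sample size {n} exceeds deme size {cfg.deme_size}"
            )
        metas.append(meta)
        pick = np.sort(rng.choice(cfg.deme_size, size=n, replace=False))
        seqs = eng.haplotype_bytes(mt[deme_idx][pick])
        for k, (row, seq) in enumerate(zip(geno[deme_idx][pick], seqs)):
            ind = f"{site_id}_{k + 1:03d}"
            individuals.append(ind)
            site_of.append(site_id)
            allele_rows.append(row)
            hap_ids.append(ind)
            hap_rows.append(seq)
            individual_deme[ind] = demes[deme_idx].name

    loci = tuple(f"L{i + 1:02d}" for i in range(cfg.n_msat_loci))
    table = GenotypeTable(
        tuple(individuals), tuple(site_of), loci, np.stack(allele_rows)
    )
    haps = HaplotypeSet(tuple(hap_ids), np.stack(hap_rows))
    dataset = StudyDataset(table, haps, tuple(metas))

    transferred: dict[str, str] = {}
    if cfg.t_split > 0:
        for j, lat in enumerate(cfg.latitudes):
            if cfg.cutoffs[j] is not None:
                transferred[lat] = f"C{j}"
    truth = SimulationTruth(
        config=cfg,
        deme_names=tuple(d.name for d in demes),
        deme_bank_current=tuple(
            (
                "east"
                if d.kind == "loop"
                and _loop_state(cfg, d.loop_index, max(cfg.t_split - 1, 0)) == "east"
                else d.bank
            )
            for d in demes
        ),
        deme_bank_precutoff=tuple(d.bank for d in demes),
        transferred_demes=transferred,
        individual_deme=individual_deme,
        parent_counts=counts,
    )
    return dataset, truth


def truth_migration_matrix(truth: SimulationTruth, window: int) -> np.ndarray:
    """Realised parent-origin fractions over the last ``window`` generations.

    Row ``d`` gives the fraction of deme ``d``'s parent lineages drawn from
    each source deme (self included); rows sum to 1.
    """
    total = truth.parent_counts.shape[0]
    if truth.config.t_split == 0:
        raise ValueError("no post-split generations were simulated")
    if not 1 <= window <= total:
        raise ValueError(f"window must be in [1, {total}]")
    summed = truth.parent_counts[total - window :].sum(axis=0).astype(float)
    rows = summed.sum(axis=1, keepdims=True)
    return summed / rows


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

_FIXTURES = ("tiny", "paper_shape", "no_cutoff_null")

#: sample sizes of the 11 pooled analysis sites of the emulated field study
_PAPER_SHAPE_SIZES = {
    "north_cis": 30,
    "north_trans": 22,
    "north_control": 29,
    "central_cis": 28,
    "central_trans": 28,
    "central_control": 21,
    "south_cis": 25,
    "south_trans": 25,
    "south_control": 25,
    "west_pure": 15,
    "east_pure": 12,
}

#: parent site -> (second sampling location, size of second location)
_PAPER_SHAPE_SPLITS = {
    "north_cis": ("north_cis2", 15),
    "south_cis": ("south_cis_b", 12),
    "south_trans": ("south_trans_b", 12),
    "south_control": ("south_control_b", 12),
}


def _paper_shape_config(seed: int, null: bool) -> SimulationConfig:
    return SimulationConfig(
        demes_per_bank=5,
        t_split=0 if null else 500,
        t_cutoff=None if null else (24, 20, 12),
        t_iso=0 if null else (12, 10, 6),
        loop_positions=(1, 2, 3),
        sample_overrides=_PAPER_SHAPE_SIZES,
        n_ancestral=240,
        seed=seed,
    )


def _split_locations(dataset: StudyDataset, rng: np.random.Generator) -> StudyDataset:
    """Split configured parent sites into two member sampling locations.

    The pooled table is unchanged; the raw table carries location labels so
    the study round-trips through files exactly like field data with
    multi-location sites.
    """
    table = dataset.genotypes
    raw_site_of = list(table.site_of)
    metas = list(dataset.sites)
    for parent, (loc_b, n_b) in _PAPER_SHAPE_SPLITS.items():
        idx = [i for i, s in enumerate(raw_site_of) if s == parent]
        if len(idx) <= n_b:
            continue
        chosen = rng.choice(len(idx), size=n_b, replace=False)
        for c in chosen:
            raw_site_of[idx[c]] = loc_b
        pmeta = dataset.site(parent)
        metas = [
            replace(m, members=(loc_b,)) if m.site_id == parent else m
            for m in metas
        ]
        metas.append(replace(pmeta, site_id=loc_b, members=()))
    raw = GenotypeTable(table.individuals, tuple(raw_site_of), table.loci, table.alleles)
    return StudyDataset(table, dataset.haplotypes, tuple(metas), raw_genotypes=raw)


def make_fixture(name: str, seed: int | None = None) -> tuple[StudyDataset, SimulationTruth]:
    """Named, internally seeded study fixtures.

    * ``tiny`` — 2 pure sites x 8 individuals x 3 loci, for unit tests;
    * ``paper_shape`` — 15 sampling locations pooling to 11 analysis sites,
      260 individuals, 13 loci, three oxbows of decreasing age;
    * ``no_cutoff_null`` — the same sampling layout with no bank split and
      no transfer event, so every site is drawn from one panmictic pool and
      the cis/trans/control labels are arbitrary (false-positive control).

    ``seed`` overrides the fixed internal seed (used for replicate suites).
    """
    if name == "tiny":
        cfg = SimulationConfig(
            deme_size=30,
            demes_per_bank=1,
            t_split=30,
            t_cutoff=None,
            t_iso=0,
            loop_positions=(),
            n_msat_loci=3,
            sample_sizes={"pure": 8},
            n_ancestral=60,
            ancestral_burnin=20,
            seed=101 if seed is None else seed,
        )
        return simulate_study(cfg)
    if name == "paper_shape":
        cfg = _paper_shape_config(202 if seed is None else seed, null=False)
        dataset, truth = simulate_study(cfg)
        rng = np.random.default_rng(cfg.seed + 7)
        return _split_locations(dataset, rng), truth
    if name == "no_cutoff_null":
        cfg = _paper_shape_config(303 if seed is None else seed, null=True)
        dataset, truth = simulate_study(cfg)
        rng = np.random.default_rng(cfg.seed + 7)
        return _split_locations(dataset, rng), truth
    raise ValueError(f"unknown fixture {name!r}; options: {', '.join(_FIXTURES)}")


# ---------------------------------------------------------------------------
# drift diagnostics
# ---------------------------------------------------------------------------


def isolated_heterozygosity_trajectory(
    deme_size: int,
    n_loci: int,
    generations: int,
    replicates: int,
    seed: int = 0,
    init_allele_sd: float = 4.0,
) -> np.ndarray:
    """Mean gene diversity per generation for isolated, mutation-free demes.

    Runs ``replicates`` independent Wright–Fisher demes with no migration
    and no mutation and returns the across-replicate mean of the per-locus
    gene diversity ``1 - sum p^2`` at each generation (length
    ``generations + 1``).  Under pure drift the expectation decays by the
    factor ``1 - 1/(2N)`` per generation.
    """
    cfg = SimulationConfig(
        deme_size=deme_size,
        demes_per_bank=1,
        t_split=0,
        t_cutoff=None,
        t_iso=0,
        loop_positions=(),
        n_msat_loci=n_loci,
        msat_mut_rate=0.0,
        mtdna_mut_rate=0.0,
        init_allele_sd=init_allele_sd,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    eng = _Engine(cfg, rng)
    lo, hi = cfg.msat_bounds
    centre = (lo + hi) / 2
    geno = np.rint(
        rng.normal(centre, init_allele_sd, size=(replicates, deme_size, n_loci, 2))
    ).astype(np.int16)
    np.clip(geno, lo, hi, out=geno)
    mt = np.zeros((replicates, deme_size), dtype=np.int32)
    identity = np.eye(replicates)

    def mean_h(g: np.ndarray) -> float:
        # gene diversity per deme x locus, averaged
        n_states = hi - lo + 1
        flat = g.transpose(0, 1, 3, 2).reshape(replicates, deme_size * 2, n_loci) - lo
        h = np.empty((replicates, n_loci))
        for d in range(replicates):
            for l in range(n_loci):
                c = np.bincount(flat[d, :, l], minlength=n_states)
                p = c / c.sum()
                h[d, l] = 1.0 - (p**2).sum()
        return float(h.mean())

    out = np.empty(generations + 1)
    out[0] = mean_h(geno)
    for t in range(generations):
        geno, mt = eng.step(geno, mt, identity)
        out[t + 1] = mean_h(geno)
    return out
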