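"""Readers, writers and validation for the study's data formats.

A study bundles three inputs:

* diploid microsatellite genotypes in the GENEPOP dialect (2- or 3-digit
  allele coding, one ``POP`` block per sampling site);
* aligned mtDNA sequences in FASTA (one record per individual, all records
  the same aligned length — nominally an 809-bp cytochrome-b fragment);
* a tab-delimited site-metadata table giving each site's role relative to
  an ancient meander loop (``cis`` = inside the old loop, ``trans`` = just
  outside it on the same current bank, ``control`` = directly across the
  current river, ``pure`` = distal reference population), its latitude
  group, and its bank under the current and the historical river channel.

Everything downstream consumes the merged, validated :class:`StudyDataset`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: sentinel allele code for a missing genotype (both slots 0)
MISSING = 0

ROLES = ("cis", "trans", "control", "pure")
LATITUDES = ("north", "central", "south", "none")
BANKS = ("west", "east")

_DNA_ALPHABET = frozenset(b"ACGTN-")


class FormatError(ValueError):
    """Malformed genotype/sequence input file."""


class MetadataError(ValueError):
    """Inconsistent or invalid site metadata."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class GenotypeTable:
    """Diploid multilocus microsatellite calls keyed by individual and site.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` and holds integer
    repeat-size allele codes; ``MISSING`` (0) in both slots marks a missing
    genotype.  A genotype is all-or-nothing missing.
    """

    individuals: tuple[str, ...]
    site_of: tuple[str, ...]
    loci: tuple[str, ...]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = tuple(self.individuals)
        self.site_of = tuple(self.site_of)
        self.loci = tuple(self.loci)
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        n, nl = len(self.individuals), len(self.loci)
        if len(self.site_of) != n:
            raise ValueError("site_of length must match individuals")
        if self.alleles.shape != (n, nl, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {nl}, 2)"
            )
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual ids")
        if (self.alleles < 0).any():
            raise ValueError("allele codes must be positive or 0 (missing)")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for {self.individuals[i]} at locus "
                f"{self.loci[l]}: both alleles must be missing or both present"
            )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def site_ids(self) -> tuple[str, ...]:
        """Distinct site ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.site_of:
            seen.setdefault(s)
        return tuple(seen)

    def site_mask(self, site_id: str) -> np.ndarray:
        return np.asarray([s == site_id for s in self.site_of])

    def site_size(self, site_id: str) -> int:
        return int(self.site_mask(site_id).sum())

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            tuple(np.asarray(self.individuals)[mask]),
            tuple(np.asarray(self.site_of)[mask]),
            self.loci,
            self.alleles[mask],
        )

    def for_sites(self, site_ids: Sequence[str]) -> "GenotypeTable":
        keep = set(site_ids)
        return self.subset(np.asarray([s in keep for s in self.site_of]))

    def relabel_sites(self, mapping: Mapping[str, str]) -> "GenotypeTable":
        return GenotypeTable(
            self.individuals,
            tuple(mapping.get(s, s) for s in self.site_of),
            self.loci,
            self.alleles,
        )

    def drop_loci(self, excluded: Iterable[str]) -> "GenotypeTable":
        excluded = set(excluded)
        keep = [i for i, l in enumerate(self.loci) if l not in excluded]
        return GenotypeTable(
            self.individuals,
            self.site_of,
            tuple(self.loci[i] for i in keep),
            self.alleles[:, keep, :],
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.site_of == other.site_of
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass(eq=False)
class HaplotypeSet:
    """Aligned mtDNA sequences, one per individual.

    ``seqs`` has shape ``(n, alignment_length)`` with dtype ``uint8``
    (ASCII over ``A C G T N -``).
    """

    ids: tuple[str, ...]
    seqs: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        self.seqs = np.asarray(self.seqs, dtype=np.uint8)
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.ids):
            raise ValueError("seqs must be (n_ids, alignment_length)")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        bad = set(np.unique(self.seqs).tobytes()) - set(_DNA_ALPHABET)
        if bad:
            raise FormatError(
                "sequence characters outside A/C/G/T/N/-: "
                + ", ".join(chr(b) for b in sorted(bad))
            )
        self._index = {s: i for i, s in enumerate(self.ids)}

    @property
    def alignment_length(self) -> int:
        return self.seqs.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    def sequence(self, ind_id: str) -> str:
        return self.seqs[self._index[ind_id]].tobytes().decode()

    def subset(self, keep_ids: Sequence[str]) -> "HaplotypeSet":
        idx = [self._index[i] for i in keep_ids if i in self._index]
        return HaplotypeSet(tuple(self.ids[i] for i in idx), self.seqs[idx])


@dataclass(frozen=True)
class SiteMetadata:
    """Role and river-bank geometry of one sampling site.

    ``members`` lists sampling-location ids pooled into this site at load
    time (e.g. two nearby cis locations combined to raise sample size).
    """

    site_id: str
    role: str
    latitude_group: str
    bank_current: str
    bank_historical: str
    oxbow_id: str | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MetadataError(f"{self.site_id}: unknown role {self.role!r}")
        if self.latitude_group not in LATITUDES:
            raise MetadataError(
                f"{self.site_id}: unknown latitude_group "
                f"{self.latitude_group!r}"
            )
        for b in (self.bank_current, self.bank_historical):
            if b not in BANKS:
                raise MetadataError(f"{self.site_id}: unknown bank {b!r}")
        if (self.role == "pure") != (self.latitude_group == "none"):
            raise MetadataError(
                f"{self.site_id}: role=pure iff latitude_group=none"
            )
        if self.role == "cis":
            if self.bank_current == self.bank_historical:
                raise MetadataError(
                    f"{self.site_id}: cis site must change banks "
                    "(bank_current == bank_historical)"
                )
        elif self.bank_current != self.bank_historical:
            raise MetadataError(
                f"{self.site_id}: only cis sites change banks"
            )


@dataclass(eq=False)
class StudyDataset:
    """Validated, merged study object consumed by every analysis stage.

    ``genotypes`` carries pooled site labels (member sampling locations
    merged into their parent site); ``raw_genotypes``, when distinct,
    retains the original location labels so the among-location AMOVA that
    justifies pooling can still be run.
    """

    genotypes: GenotypeTable
    haplotypes: HaplotypeSet
    sites: tuple[SiteMetadata, ...]
    raw_genotypes: GenotypeTable | None = None

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        known = {s.site_id for s in self.sites}
        for ind, site in zip(self.genotypes.individuals, self.genotypes.site_of):
            if site not in known:
                raise MetadataError(
                    f"individual {ind} references unknown site {site!r}"
                )
        geno_ids = set(self.genotypes.individuals)
        extra = [i for i in self.haplotypes.ids if i not in geno_ids]
        if extra:
            raise MetadataError(
                f"sequences for unknown individuals: {', '.join(extra[:5])}"
            )
        self._meta = {s.site_id: s for s in self.sites}
        if self.raw_genotypes is None:
            self.raw_genotypes = self.genotypes

    def site(self, site_id: str) -> SiteMetadata:
        return self._meta[site_id]

    @property
    def consumed_locations(self) -> frozenset[str]:
        """Sampling-location ids pooled into a parent site."""
        out: set[str] = set()
        for s in self.sites:
            out.update(s.members)
        return frozenset(out)

    @property
    def analysis_sites(self) -> tuple[SiteMetadata, ...]:
        """Sites that carry individuals after pooling (analysis units)."""
        consumed = self.consumed_locations
        present = set(self.genotypes.site_ids)
        return tuple(
            s
            for s in self.sites
            if s.site_id not in consumed and s.site_id in present
        )

    def sites_by_role(self, role: str, latitude: str | None = None) -> list[SiteMetadata]:
        out = [s for s in self.analysis_sites if s.role == role]
        if latitude is not None:
            out = [s for s in out if s.latitude_group == latitude]
        return out

    def pure_site(self, bank: str) -> SiteMetadata:
        for s in self.analysis_sites:
            if s.role == "pure" and s.bank_current == bank:
                return s
        raise MetadataError(f"no pure site on bank {bank!r}")

    @property
    def latitudes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.analysis_sites:
            if s.latitude_group != "none":
                seen.setdefault(s.latitude_group)
        return tuple(seen)

    def triplet(self, latitude: str) -> dict[str, SiteMetadata]:
        """The cis/trans/control sites of one latitude."""
        out = {}
        for role in ("cis", "trans", "control"):
            hits = self.sites_by_role(role, latitude)
            if len(hits) == 1:
                out[role] = hits[0]
            elif hits:
                raise MetadataError(
                    f"{latitude}: multiple {role} sites after pooling"
                )
        return out

    def site_of_individual(self, ind_id: str) -> str:
        idx = self.genotypes.individuals.index(ind_id)
        return self.genotypes.site_of[idx]


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------

_SITES_RE = re.compile(r"sites=([^;]+)")


def read_genepop(path: str | Path) -> GenotypeTable:
    """Parse a GENEPOP file (2- or 3-digit coding) into a GenotypeTable.

    One site per ``POP`` block.  ``00``/``000`` allele codes are missing; a
    genotype with exactly one missing allele is demoted to fully missing
    with a warning.  Site names are taken from a ``sites=a,b,c`` clause in
    the title line when present (the convention written by
    :func:`write_genepop`), else ``pop_1 .. pop_k``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    title = lines[0]
    m = _SITES_RE.search(title)
    declared_sites = (
        [s.strip() for s in m.group(1).split(",") if s.strip()] if m else None
    )

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        row = lines[i].strip()
        if not row:
            raise FormatError(f"{path}: line {i + 1}: blank locus line")
        parts = [p.strip() for p in row.split(",") if p.strip()]
        for p in parts:
            if " " in p or "\t" in p:
                raise FormatError(
                    f"{path}: line {i + 1}: malformed locus name {p!r}"
                )
        loci.extend(parts)
        i += 1
    if not loci:
        raise FormatError(f"{path}: no locus declarations before first POP")

    individuals: list[str] = []
    site_of: list[str] = []
    rows: list[list[int]] = []
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        row = lines[i].strip()
        i += 1
        if not row:
            continue
        if pop_idx == 0:
            raise FormatError(f"{path}: genotype row before first POP")
        if "," not in row:
            raise FormatError(
                f"{path}: line {i}: missing ',' between name and genotypes"
            )
        name, geno_part = row.split(",", 1)
        name = name.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise FormatError(
                f"{path}: individual {name!r} has {len(tokens)} genotypes, "
                f"expected {len(loci)}"
            )
        calls: list[int] = []
        for tok, locus in zip(tokens, loci):
            if not tok.isdigit() or len(tok) not in (4, 6):
                raise FormatError(
                    f"{path}: individual {name!r}, locus {locus}: "
                    f"bad genotype token {tok!r}"
                )
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            if (a == 0) != (b == 0):
                logger.warning(
                    "%s: %s at %s is half-missing (%s); treated as missing",
                    path, name, locus, tok,
                )
                a = b = MISSING
            calls.extend((a, b))
        individuals.append(name)
        if declared_sites and pop_idx <= len(declared_sites):
            site_of.append(declared_sites[pop_idx - 1])
        else:
            site_of.append(f"pop_{pop_idx}")
        rows.append(calls)

    alleles = (
        np.asarray(rows, dtype=np.int32).reshape(len(rows), len(loci), 2)
        if rows
        else np.zeros((0, len(loci), 2), dtype=np.int32)
    )
    return GenotypeTable(tuple(individuals), tuple(site_of), tuple(loci), alleles)


def write_genepop(
    table: GenotypeTable,
    sites: Sequence[SiteMetadata] | Sequence[str] | None,
    path: str | Path,
    title: str = "oxbowflow export",
) -> Path:
    """Write a GenotypeTable as 3-digit GENEPOP.

    Site blocks follow metadata order (then any remaining table sites in
    first-appearance order); individuals are sorted lexically inside each
    block so output is deterministic.  Allele codes above 999 are refused.
    """
    path = Path(path)
    if table.alleles.max(initial=0) > 999:
        raise ValueError("allele code > 999 cannot be written in 3-digit GENEPOP")
    ordered: list[str] = []
    if sites is not None:
        for s in sites:
            sid = s.site_id if isinstance(s, SiteMetadata) else str(s)
            if sid in table.site_ids:
                ordered.append(sid)
    for sid in table.site_ids:
        if sid not in ordered:
            ordered.append(sid)

    out = [f"{title}; sites={','.join(ordered)}"]
    out.extend(table.loci)
    site_arr = np.asarray(table.site_of)
    for sid in ordered:
        out.append("POP")
        idx = np.flatnonzero(site_arr == sid)
        idx = idx[np.argsort(np.asarray(table.individuals)[idx])]
        for i in idx:
            toks = [
                f"{a:03d}{b:03d}" for a, b in table.alleles[i]
            ]
            out.append(f"{table.individuals[i]} ,  " + " ".join(toks))
    path.write_text("\n".join(out) + "\n")
    return path


def write_structure(table: GenotypeTable, path: str | Path) -> Path:
    """Export the STRUCTURE matrix dialect: one row per individual,
    two columns per locus, ``-9`` for missing."""
    path = Path(path)
    site_index = {s: k + 1 for k, s in enumerate(table.site_ids)}
    header = "\t".join(
        ["individual", "site"] + [f"{l}_{j}" for l in table.loci for j in (1, 2)]
    )
    rows = [header]
    for i, ind in enumerate(table.individuals):
        calls = [
            str(a) if a != MISSING else "-9" for a in table.alleles[i].ravel()
        ]
        rows.append(
            "\t".join([ind, str(site_index[table.site_of[i]])] + calls)
        )
    path.write_text("\n".join(rows) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> HaplotypeSet:
    """Read an aligned FASTA into a HaplotypeSet.

    IDs are the header up to the first whitespace; bases are upper-cased.
    Unequal record lengths and duplicate IDs are errors.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[bytes] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper().encode())
    if not ids:
        raise FormatError(f"{path}: no FASTA records")
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate record id(s): {', '.join(dup)}")
    length = len(seqs[0])
    for rid, s in zip(ids, seqs):
        if len(s) != length:
            raise FormatError(
                f"{path}: record {rid} has length {len(s)}, expected {length}"
            )
    arr = np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(len(ids), length)
    return HaplotypeSet(tuple(ids), arr.copy())


def write_fasta(haps: HaplotypeSet, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, rid in enumerate(haps.ids):
            fh.write(f">{rid}\n")
            s = haps.seqs[i].tobytes().decode()
            for j in range(0, len(s), width):
                fh.write(s[j : j + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# metadata + merged study
# ---------------------------------------------------------------------------

_META_COLUMNS = (
    "site_id",
    "role",
    "latitude_group",
    "bank_current",
    "bank_historical",
)


def read_site_metadata(path: str | Path) -> tuple[SiteMetadata, ...]:
    """Read the tab-delimited site table (UTF-8; optional ``oxbow_id`` and
    comma-separated ``members`` columns)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing columns: {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        members = tuple(
            m.strip()
            for m in str(row.get("members", "")).split(",")
            if m.strip()
        )
        out.append(
            SiteMetadata(
                site_id=row["site_id"],
                role=row["role"],
                latitude_group=row["latitude_group"],
                bank_current=row["bank_current"],
                bank_historical=row["bank_historical"],
                oxbow_id=(row.get("oxbow_id") or None),
                members=members,
            )
        )
    if len({s.site_id for s in out}) != len(out):
        raise MetadataError(f"{path}: duplicate site_id")
    return tuple(out)


def write_site_metadata(sites: Sequence[SiteMetadata], path: str | Path) -> Path:
    rows = ["\t".join(_META_COLUMNS + ("oxbow_id", "members"))]
    for s in sites:
        rows.append(
            "\t".join(
                [
                    s.site_id,
                    s.role,
                    s.latitude_group,
                    s.bank_current,
                    s.bank_historical,
                    s.oxbow_id or "",
                    ",".join(s.members),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")
    return Path(path)


def pool_member_locations(
    table: GenotypeTable, sites: Sequence[SiteMetadata]
) -> GenotypeTable:
    """Relabel member sampling locations to their pooled parent site.

    Pooling multiple nearby sampling locations into one analysis site is
    legitimate only when an among-location AMOVA finds no differentiation;
    :func:`oxbowflow.popgen_stats.amova_pooling_check` performs that test
    on the unpooled table.
    """
    mapping: dict[str, str] = {}
    for s in sites:
        for m in s.members:
            if m in mapping:
                raise MetadataError(f"location {m} claimed by two parent sites")
            mapping[m] = s.site_id
    return table.relabel_sites(mapping) if mapping else table


def load_study(
    genotype_path: str | Path,
    fasta_path: str | Path | None,
    metadata_path: str | Path,
) -> StudyDataset:
    """Read, cross-reference and validate the three study inputs.

    Individuals lacking a sequence are retained (their haplotype is simply
    absent).  Member sampling locations declared in metadata are pooled
    into their parent site.  No individual is ever silently dropped: any
    reject raises.
    """
    raw = read_genepop(genotype_path)
    sites = read_site_metadata(metadata_path)
    table = pool_member_locations(raw, sites)

    n_before = table.n_individuals
    known = {s.site_id for s in sites}
    unknown = sorted({s for s in table.site_of if s not in known})
    if unknown:
        raise MetadataError(
            f"genotype site(s) not in metadata: {', '.join(unknown)}"
        )

    if fasta_path is not None:
        haps = read_fasta(fasta_path)
    else:
        haps = HaplotypeSet((), np.zeros((0, 0), dtype=np.uint8))

    study = StudyDataset(table, haps, tuple(sites), raw_genotypes=raw)
    assert study.genotypes.n_individuals == n_before  # nothing dropped

    # QC: warn on loci >50% missing within a site (never excluded).
    for sid in table.site_ids:
        mask = table.site_mask(sid)
        sub = table.alleles[mask]
        miss = (sub[:, :, 0] == MISSING).mean(axis=0)
        for l, frac in zip(table.loci, miss):
            if frac > 0.5:
                logger.warning(
                    "site %s locus %s: %.0f%% missing genotypes", sid, l,
                    100 * frac,
                )
    return study


# ---------------------------------------------------------------------------
# QC arithmetic
# ---------------------------------------------------------------------------


def genotyping_error_rate(n_mismatch: int, n_reactions: int) -> float:
    """Per-reaction genotyping error rate from re-genotyped samples:
    mismatched genotypes divided by total re-genotyped reactions."""
    if n_reactions <= 0:
        raise ValueError("error rate undefined for n_reactions <= 0")
    if not 0 <= n_mismatch <= n_reactions:
        raise ValueError("need 0 <= n_mismatch <= n_reactions")
    return n_mismatch / n_reactions
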