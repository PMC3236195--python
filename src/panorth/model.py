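"""Core domain types: CDSs, genomes, taxonomy, and the pair/group records
every pipeline stage exchanges.

Conventions
-----------
* Coordinates are 1-based inclusive (GenBank convention).
* Protein sequences are uppercase amino-acid strings; the stop symbol ``*``
  is permitted (some annotation pipelines retain it) and a trailing stop is
  stripped before alignment, never on ingest.
* Ortholog/paralog pairs are stored with canonically ordered CDS ids
  (lexicographic), so pair collections compare as sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

#: Taxonomic ranks ordered from most to least specific.  "species" is the
#: lowest rank at which orthologs are called; "domain" is the root.
RANKS: tuple[str, ...] = (
    "species",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "domain",
)

RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Provenance labels for ortholog pairs.
PROVENANCES: tuple[str, ...] = ("species_bbh", "explicit", "implicit")


class PanorthError(Exception):
    """Base class for all package errors."""


class FormatError(PanorthError):
    """Malformed on-disk input (FASTA, manifest, pairs table...)."""


class IntegrityError(PanorthError):
    """Internally inconsistent data (duplicate ids, dangling references...)."""


class UsageError(PanorthError):
    """An operation was invoked with arguments that make no sense."""


@dataclass(frozen=True)
class CDS:
    """A single protein-coding sequence with genome membership.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates on
    ``contig``; all three (plus ``strand``) may be absent for inputs without
    positional annotation, in which case synteny detection falls back to
    anchor counting.
    """

    cds_id: str
    genome_id: str
    protein_seq: str
    contig: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise IntegrityError(f"CDS {self.cds_id!r}: empty protein sequence")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise IntegrityError(
                f"CDS {self.cds_id!r}: end ({self.end}) < start ({self.start})"
            )
        if self.strand is not None and self.strand not in ("+", "-"):
            raise IntegrityError(f"CDS {self.cds_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        """Residue count, ignoring a trailing stop symbol."""
        seq = self.protein_seq
        return len(seq) - 1 if seq.endswith("*") else len(seq)

    @property
    def has_coordinates(self) -> bool:
        return self.contig is not None and self.start is not None and self.end is not None


@dataclass
class Genome:
    """One annotated genome: an id, a seven-rank lineage and its CDS ids."""

    genome_id: str
    lineage: dict[str, str]
    cds_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineage]
        if missing:
            raise FormatError(
                f"genome {self.genome_id!r}: lineage missing rank(s) {missing}"
            )

    def taxon(self, rank: str) -> tuple[str, str]:
        return (rank, self.lineage[rank])


@dataclass(frozen=True)
class SimilarityHit:
    """A pairwise local-alignment result.

    ``identity`` is the percentage of identical column pairs over aligned
    columns (gap columns included in the denominator); ``coverage`` is the
    percentage of the *shorter* sequence's residues inside the alignment.
    Both are symmetric under query/subject swap, as is ``score``.
    """

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    score: float
    evalue: float
    aligned_length: int

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 100.0):
            raise IntegrityError(f"identity out of (0,100]: {self.identity}")
        if not (0.0 < self.coverage <= 100.0):
            raise IntegrityError(f"coverage out of (0,100]: {self.coverage}")
        if self.evalue < 0:
            raise IntegrityError(f"negative e-value: {self.evalue}")

    def swapped(self) -> "SimilarityHit":
        return SimilarityHit(
            self.subject_id,
            self.query_id,
            self.identity,
            self.coverage,
            self.score,
            self.evalue,
            self.aligned_length,
        )


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order two CDS ids lexicographically (the canonical pair form)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class OrthologPair:
    """A cross-genome ortholog pair, tagged with the taxonomic rank at which
    it was detected and how (species-level BBH, explicit clustering of
    pan-genome entries, or implicit expansion of an explicit pair)."""

    cds_a: str
    cds_b: str
    level: str
    provenance: str

    def __post_init__(self) -> None:
        if self.cds_a >= self.cds_b:
            raise IntegrityError(
                f"pair ({self.cds_a}, {self.cds_b}) not canonically ordered"
            )
        if self.level not in RANK_INDEX:
            raise IntegrityError(f"unknown rank {self.level!r}")
        if self.provenance not in PROVENANCES:
            raise IntegrityError(f"unknown provenance {self.provenance!r}")

    @staticmethod
    def make(a: str, b: str, level: str, provenance: str) -> "OrthologPair":
        a, b = canonical_pair(a, b)
        return OrthologPair(a, b, level, provenance)

    @property
    def key(self) -> tuple[str, str]:
        return (self.cds_a, self.cds_b)


@dataclass(frozen=True)
class ParalogPair:
    """A within-genome pair; only the best-scoring alignment is kept."""

    cds_a: str
    cds_b: str
    hit: SimilarityHit

    def __post_init__(self) -> None:
        if self.cds_a >= self.cds_b:
            raise IntegrityError(
                f"paralog pair ({self.cds_a}, {self.cds_b}) not canonically ordered"
            )

    @staticmethod
    def make(a: str, b: str, hit: SimilarityHit) -> "ParalogPair":
        if a > b:
            a, b = b, a
            hit = hit.swapped()
        return ParalogPair(a, b, hit)

    @property
    def key(self) -> tuple[str, str]:
        return (self.cds_a, self.cds_b)


class TaxonomyTree:
    """The rank hierarchy over a genome collection.

    Nodes are keyed by ``(rank, name)``; children link downward
    (domain -> phylum -> ... -> species); genome ids hang off species leaves.
    """

    def __init__(self) -> None:
        self.children: dict[tuple[str, str], set[tuple[str, str]]] = {}
        self.parent: dict[tuple[str, str], tuple[str, str]] = {}
        self.genomes_at_species: dict[tuple[str, str], list[str]] = {}

    def add_genome(self, genome: Genome) -> None:
        lineage = genome.lineage
        # walk root-ward: species -> genus -> ... -> domain
        for lower, upper in zip(RANKS[:-1], RANKS[1:]):
            child = (lower, lineage[lower])
            par = (upper, lineage[upper])
            existing = self.parent.get(child)
            if existing is not None and existing != par:
                raise IntegrityError(
                    f"lineage conflict: taxon {child} has parents {existing} and {par}"
                )
            self.parent[child] = par
            self.children.setdefault(par, set()).add(child)
            self.children.setdefault(child, set())
        sp = ("species", lineage["species"])
        self.genomes_at_species.setdefault(sp, [])
        if genome.genome_id not in self.genomes_at_species[sp]:
            self.genomes_at_species[sp].append(genome.genome_id)

    def taxa_at_rank(self, rank: str) -> list[tuple[str, str]]:
        if rank not in RANK_INDEX:
            raise UsageError(f"unknown rank {rank!r}")
        taxa = {k for k in self.children if k[0] == rank}
        taxa |= {k for k in self.parent if k[0] == rank}
        return sorted(taxa)

    def children_of(self, taxon: tuple[str, str]) -> list[tuple[str, str]]:
        return sorted(self.children.get(taxon, ()))

    def genomes_under(self, taxon: tuple[str, str]) -> list[str]:
        """All genome ids in the subtree below (or at) ``taxon``."""
        rank, _ = taxon
        if rank == "species":
            return list(self.genomes_at_species.get(taxon, []))
        out: list[str] = []
        for child in self.children_of(taxon):
            out.extend(self.genomes_under(child))
        return out

    def roots(self) -> list[tuple[str, str]]:
        return self.taxa_at_rank("domain")


@dataclass
class HomologGroup:
    """A single-linkage group of homologous CDSs with a chosen representative."""

    group_id: str
    members: list[str]
    representative: str

    def __post_init__(self) -> None:
        if not self.members:
            raise UsageError(f"group {self.group_id!r}: empty member list")
        if self.representative not in self.members:
            raise IntegrityError(
                f"group {self.group_id!r}: representative not a member"
            )


@dataclass
class PanGenome:
    """A reduced proxy CDS set for a taxon.

    ``entries`` lists one CDS id per homolog group (singletons represent
    themselves); ``rep_to_members`` maps every entry to the full, flattened
    list of CDSs it stands for, so the value-lists partition the taxon's
    input CDS collection.
    """

    taxon: tuple[str, str]
    entries: list[str]
    rep_to_members: dict[str, list[str]]

    def __post_init__(self) -> None:
        if set(self.entries) != set(self.rep_to_members):
            raise IntegrityError(
                f"pan-genome {self.taxon}: entries and rep_to_members disagree"
            )
        seen: set[str] = set()
        for rep, members in self.rep_to_members.items():
            if rep not in members:
                raise IntegrityError(f"pan-genome {self.taxon}: {rep} not in its members")
            for m in members:
                if m in seen:
                    raise IntegrityError(
                        f"pan-genome {self.taxon}: CDS {m} represented twice"
                    )
                seen.add(m)

    @property
    def all_members(self) -> set[str]:
        return {m for ms in self.rep_to_members.values() for m in ms}

    def __len__(self) -> int:
        return len(self.entries)


def dedupe_pairs(pairs: Iterable[OrthologPair]) -> list[OrthologPair]:
    """Drop duplicate canonical pairs, keeping first occurrence."""
    seen: set[tuple[str, str]] = set()
    out: list[OrthologPair] = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            out.append(p)
    return out


def lca_rank(genome_a: Genome, genome_b: Genome) -> Optional[str]:
    """Lowest rank at which two genomes share a taxon name, or None."""
    for rank in RANKS:
        if genome_a.lineage[rank] == genome_b.lineage[rank]:
            return rank
    return None
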