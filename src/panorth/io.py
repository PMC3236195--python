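"""Readers and writers for the on-disk formats.

Formats: protein FASTA (one record per CDS, id = first header token),
a genome manifest TSV (genome id, seven lineage columns, FASTA path, and an
optional per-CDS coordinate table), pair TSVs, group TSVs and pan-genome
TSVs.  All writers produce deterministic, diff-friendly output.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .model import (
    CDS,
    FormatError,
    Genome,
    HomologGroup,
    IntegrityError,
    OrthologPair,
    PanGenome,
    PROVENANCES,
    RANKS,
    TaxonomyTree,
)

MANIFEST_COLUMNS = ["genome_id", *RANKS, "fasta_path"]
PAIR_COLUMNS = ["cds_a", "cds_b", "level", "provenance"]


def read_protein_fasta(path: str, genome_id: str) -> list[CDS]:
    """Read one genome's protein FASTA into CDS records.

    The first whitespace-delimited header token is the CDS id; the rest of
    the description (if any) becomes the product annotation.  Sequences are
    uppercased; record order is preserved.
    """
    records: list[CDS] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(path, "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"cannot parse FASTA {path!r}: {exc}") from exc
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in (">", ";"):
            raise FormatError(f"{path!r}: not FASTA (first character {first!r})")
    for rec in parsed:
        if rec.id in seen:
            raise IntegrityError(f"{path!r}: duplicate CDS id {rec.id!r}")
        seen.add(rec.id)
        product = rec.description.partition(" ")[2].strip() or None
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path!r}: record {rec.id!r} has an empty sequence")
        records.append(
            CDS(cds_id=rec.id, genome_id=genome_id, protein_seq=seq, product=product)
        )
    return records


def write_protein_fasta(cdss: Sequence[CDS], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for cds in cdss:
            header = cds.cds_id if cds.product is None else f"{cds.cds_id} {cds.product}"
            fh.write(f">{header}\n")
            for i in range(0, len(cds.protein_seq), width):
                fh.write(cds.protein_seq[i : i + width] + "\n")


def read_coordinates(path: str) -> dict[str, tuple[str, int, int, str]]:
    """Read an optional per-CDS coordinate TSV: cds_id, contig, start, end, strand."""
    out: dict[str, tuple[str, int, int, str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"cds_id", "contig", "start", "end", "strand"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path!r}: coordinate table needs columns {sorted(required)}")
        for row in reader:
            out[row["cds_id"]] = (
                row["contig"],
                int(row["start"]),
                int(row["end"]),
                row["strand"],
            )
    return out


def write_coordinates(cdss: Sequence[CDS], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cds_id\tcontig\tstart\tend\tstrand\n")
        for c in cdss:
            if c.has_coordinates:
                fh.write(f"{c.cds_id}\t{c.contig}\t{c.start}\t{c.end}\t{c.strand}\n")


def read_manifest(
    path: str,
) -> tuple[list[Genome], TaxonomyTree, dict[str, CDS]]:
    """Read the genome manifest and all FASTAs it points to.

    Returns the genomes (manifest order), the taxonomy tree and a global
    CDS map.  FASTA paths are resolved relative to the manifest's directory.
    A sibling ``<fasta>.coords.tsv`` file, when present, supplies contig
    coordinates for synteny detection.
    """
    base = os.path.dirname(os.path.abspath(path))
    genomes: list[Genome] = []
    cds_map: dict[str, CDS] = {}
    tree = TaxonomyTree()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path!r}: empty manifest")
        missing = [c for c in MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path!r}: manifest missing column(s) {missing}")
        for row in reader:
            gid = row["genome_id"]
            if any(g.genome_id == gid for g in genomes):
                raise IntegrityError(f"{path!r}: duplicate genome id {gid!r}")
            lineage = {r: row[r] for r in RANKS}
            for r, name in lineage.items():
                if not name:
                    raise FormatError(f"{path!r}: genome {gid!r} missing rank {r!r}")
            fasta = row["fasta_path"]
            if not os.path.isabs(fasta):
                fasta = os.path.join(base, fasta)
            cdss = read_protein_fasta(fasta, gid)
            coords_path = fasta + ".coords.tsv"
            if os.path.exists(coords_path):
                coords = read_coordinates(coords_path)
                cdss = [
                    CDS(
                        c.cds_id,
                        c.genome_id,
                        c.protein_seq,
                        *(coords[c.cds_id] if c.cds_id in coords else (None, None, None, None)),
                        product=c.product,
                    )
                    for c in cdss
                ]
            for c in cdss:
                if c.cds_id in cds_map:
                    raise IntegrityError(
                        f"CDS id {c.cds_id!r} occurs in two genomes "
                        f"({cds_map[c.cds_id].genome_id!r} and {gid!r})"
                    )
                cds_map[c.cds_id] = c
            genome = Genome(genome_id=gid, lineage=lineage, cds_ids=[c.cds_id for c in cdss])
            if not genome.cds_ids:
                raise IntegrityError(f"genome {gid!r}: no CDS records")
            tree.add_genome(genome)
            genomes.append(genome)
    return genomes, tree, cds_map


def write_pairs(pairs: Iterable[OrthologPair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in sorted(pairs, key=lambda p: (p.level, p.cds_a, p.cds_b)):
            fh.write(f"{p.cds_a}\t{p.cds_b}\t{p.level}\t{p.provenance}\n")


def read_pairs(path: str) -> list[OrthologPair]:
    out: list[OrthologPair] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != PAIR_COLUMNS:
            raise FormatError(f"{path!r}: expected columns {PAIR_COLUMNS}")
        for row in reader:
            if row["provenance"] not in PROVENANCES:
                raise FormatError(f"{path!r}: unknown provenance {row['provenance']!r}")
            out.append(
                OrthologPair.make(row["cds_a"], row["cds_b"], row["level"], row["provenance"])
            )
    return out


def write_groups(groups: Iterable[HomologGroup], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\trepresentative\tmembers\n")
        for g in sorted(groups, key=lambda g: g.group_id):
            fh.write(f"{g.group_id}\t{g.representative}\t{','.join(sorted(g.members))}\n")


def read_groups(path: str) -> list[HomologGroup]:
    out: list[HomologGroup] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ["group_id", "representative", "members"]:
            raise FormatError(f"{path!r}: bad group table header")
        for row in reader:
            out.append(
                HomologGroup(
                    row["group_id"], row["members"].split(","), row["representative"]
                )
            )
    return out


def write_pangenome(pg: PanGenome, path: str) -> None:
    rank, name = pg.taxon
    with open(path, "w") as fh:
        fh.write("taxon_rank\ttaxon_name\tentry\tmembers\n")
        for entry in sorted(pg.entries):
            members = ",".join(sorted(pg.rep_to_members[entry]))
            fh.write(f"{rank}\t{name}\t{entry}\t{members}\n")


def read_pangenome(path: str) -> PanGenome:
    taxon: Optional[tuple[str, str]] = None
    entries: list[str] = []
    rep_to_members: dict[str, list[str]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != ["taxon_rank", "taxon_name", "entry", "members"]:
            raise FormatError(f"{path!r}: bad pan-genome table header")
        for row in reader:
            t = (row["taxon_rank"], row["taxon_name"])
            if taxon is None:
                taxon = t
            elif t != taxon:
                raise FormatError(f"{path!r}: mixed taxa {taxon} and {t}")
            entries.append(row["entry"])
            rep_to_members[row["entry"]] = row["members"].split(",")
    if taxon is None:
        raise FormatError(f"{path!r}: empty pan-genome table")
    return PanGenome(taxon=taxon, entries=entries, rep_to_members=rep_to_members)
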