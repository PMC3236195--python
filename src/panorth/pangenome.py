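"""Single-linkage homolog grouping, representative selection and pan-genome
construction.

A taxon's pan-genome is a reduced proxy for its full CDS collection: every
CDS with no homolog stays in as a singleton, and each single-linkage
homolog group is replaced by one representative — the member with the most
orthologs at the level being built (ties: longer protein, then smallest
id).  Because grouping is over the full pair graph, the result does not
depend on the order in which genomes are considered.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .model import (
    CDS,
    Genome,
    HomologGroup,
    IntegrityError,
    OrthologPair,
    PanGenome,
    ParalogPair,
    SimilarityHit,
    UsageError,
)

#: identity / coverage cut for treating a same-genome pair as homologous
PARALOG_CUT = (90.0, 90.0)
#: identity / coverage cut for treating a cross-genome pair as homologous
ORTHOLOG_CUT = (70.0, 70.0)


def single_linkage(nodes: Iterable[str], edges: Iterable[tuple[str, str]]) -> list[list[str]]:
    """Partition nodes into connected components of the pair graph.

    Groups are returned sorted by their minimum member id, members sorted
    within each group — a deterministic labelling.
    """
    g = nx.Graph()
    node_set = set(nodes)
    g.add_nodes_from(node_set)
    for a, b in edges:
        if a not in node_set or b not in node_set:
            raise IntegrityError(f"edge ({a!r}, {b!r}) references unknown node")
        g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    return comps


def homology_edges(
    cds_ids: Iterable[str],
    cds_map: Mapping[str, CDS],
    paralog_pairs: Iterable[ParalogPair] = (),
    ortholog_pairs: Iterable[tuple[OrthologPair, SimilarityHit]] = (),
    paralog_cut: tuple[float, float] = PARALOG_CUT,
    ortholog_cut: tuple[float, float] = ORTHOLOG_CUT,
) -> list[tuple[str, str]]:
    """Edges of the homology graph: same-genome pairs at the paralogy cut,
    cross-genome pairs at the orthology cut (both inclusive)."""
    keep = set(cds_ids)
    pid, pcov = paralog_cut
    oid, ocov = ortholog_cut
    edges: list[tuple[str, str]] = []
    for pp in paralog_pairs:
        if pp.cds_a in keep and pp.cds_b in keep:
            if pp.hit.identity >= pid and pp.hit.coverage >= pcov:
                edges.append((pp.cds_a, pp.cds_b))
    for op, hit in ortholog_pairs:
        if op.cds_a in keep and op.cds_b in keep:
            if hit.identity >= oid and hit.coverage >= ocov:
                edges.append((op.cds_a, op.cds_b))
    return edges


def select_representative(
    group: Sequence[str],
    ortholog_count: Mapping[str, int],
    cds_map: Mapping[str, CDS],
) -> str:
    """The member with the largest ortholog count at this level; ties go to
    the longer protein, then the lexicographically smallest id."""
    if not group:
        raise UsageError("cannot pick a representative from an empty group")
    return min(
        group,
        key=lambda c: (-ortholog_count.get(c, 0), -cds_map[c].length, c),
    )


def _make_groups(
    components: list[list[str]],
    ortholog_count: Mapping[str, int],
    cds_map: Mapping[str, CDS],
    prefix: str,
) -> list[HomologGroup]:
    groups = []
    for i, comp in enumerate(components):
        rep = select_representative(comp, ortholog_count, cds_map)
        groups.append(HomologGroup(f"{prefix}{i:05d}", list(comp), rep))
    return groups


def build_species_pangenome(
    species: tuple[str, str],
    genomes: Sequence[Genome],
    cds_map: Mapping[str, CDS],
    paralog_pairs: Iterable[ParalogPair] = (),
    ortholog_pairs: Iterable[tuple[OrthologPair, SimilarityHit]] = (),
    paralog_cut: tuple[float, float] = PARALOG_CUT,
    ortholog_cut: tuple[float, float] = ORTHOLOG_CUT,
) -> tuple[PanGenome, list[HomologGroup]]:
    """Build a species pan-genome from its genomes' paralog and (for two or
    more genomes) species ortholog pairs.

    Singleton CDSs enter unchanged; each homolog group contributes the
    member with the most species-level orthologs.  Single-genome species
    reduce to their paralog groups (the orthology clause is vacuous).
    """
    cds_ids = [cid for g in sorted(genomes, key=lambda g: g.genome_id) for cid in g.cds_ids]
    if not cds_ids:
        raise UsageError(f"species {species}: no CDSs")
    edges = homology_edges(
        cds_ids, cds_map, paralog_pairs, ortholog_pairs, paralog_cut, ortholog_cut
    )
    components = single_linkage(sorted(cds_ids), edges)
    counts: dict[str, int] = {}
    for op, _hit in ortholog_pairs:
        counts[op.cds_a] = counts.get(op.cds_a, 0) + 1
        counts[op.cds_b] = counts.get(op.cds_b, 0) + 1
    groups = _make_groups(components, counts, cds_map, f"{species[1]}|HG")
    entries = sorted(g.representative for g in groups)
    rep_to_members = {g.representative: sorted(g.members) for g in groups}
    return (
        PanGenome(taxon=species, entries=entries, rep_to_members=rep_to_members),
        groups,
    )


def build_level_pangenome(
    taxon: tuple[str, str],
    child_pangenomes: Sequence[PanGenome],
    explicit_groups: Sequence[HomologGroup],
    ortholog_count: Mapping[str, int],
    cds_map: Mapping[str, CDS],
) -> PanGenome:
    """Collapse each explicit ortholog group of child pan-genome entries to
    a single representative — the member with the largest ortholog count at
    this level, explicit and implicit pairs both counted.

    Implicit orthologs influence only the representative choice, never the
    grouping: unclustered child entries pass through untouched.  The
    returned member map is flattened, so an entry always stands for the
    full set of underlying CDSs it represents.
    """
    member_map: dict[str, list[str]] = {}
    for pg in child_pangenomes:
        for rep, members in pg.rep_to_members.items():
            if rep in member_map:
                raise IntegrityError(f"entry {rep!r} occurs in two child pan-genomes")
            member_map[rep] = list(members)

    clustered: set[str] = set()
    entries: list[str] = []
    rep_to_members: dict[str, list[str]] = {}
    for grp in explicit_groups:
        for m in grp.members:
            if m not in member_map:
                raise IntegrityError(
                    f"explicit group {grp.group_id!r}: {m!r} is not a child pan-genome entry"
                )
            if m in clustered:
                raise IntegrityError(f"entry {m!r} in two explicit groups")
            clustered.add(m)
        rep = select_representative(grp.members, ortholog_count, cds_map)
        flattened = sorted({x for m in grp.members for x in member_map[m]})
        entries.append(rep)
        rep_to_members[rep] = flattened

    for rep, members in member_map.items():
        if rep not in clustered:
            entries.append(rep)
            rep_to_members[rep] = sorted(members)

    return PanGenome(taxon=taxon, entries=sorted(entries), rep_to_members=rep_to_members)
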