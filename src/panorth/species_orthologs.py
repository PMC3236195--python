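"""Synteny-aware bidirectional-best-hit (BBH) ortholog calling between two
genomes of the same species.

The classic BBH heuristic is refined by first chaining CDS-level hits into
syntenic blocks and resolving BBHs block by block, longest block first: a
BBH pair is accepted only when neither member is already paired, which
filters out co-ortholog copies lying outside syntenic blocks.  A final
genome-wide BBH pass over still-unpaired CDSs makes the operation total on
inputs without coordinates; a strict-synteny switch disables it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .align import AlignmentEngine, DEFAULT_GAP_LIMIT, syntenic_blocks
from .model import CDS, Genome, OrthologPair, SimilarityHit, UsageError


@dataclass
class SpeciesOrthologResult:
    """Ortholog pairs for one genome pair plus their supporting hits."""

    pairs: list[OrthologPair]
    hits: dict[tuple[str, str], SimilarityHit]  # canonical pair key -> hit

    def hit_for(self, pair: OrthologPair) -> SimilarityHit:
        return self.hits[pair.key]


def _best_partner(
    cds_id: str,
    partners: dict[str, list[SimilarityHit]],
) -> Optional[str]:
    """Highest score, ties by higher identity, then smaller partner id."""
    cands = partners.get(cds_id)
    if not cands:
        return None
    best = max(cands, key=lambda h: (h.score, h.identity, h.subject_id))
    # max() with a str key prefers the LARGER id; re-scan for the smallest
    # id among exact (score, identity) ties to keep the contract explicit.
    ties = [
        h
        for h in cands
        if h.score == best.score and h.identity == best.identity
    ]
    return min(t.subject_id for t in ties)


def _bbh(
    a_ids: Sequence[str],
    b_ids: Sequence[str],
    hits: Sequence[SimilarityHit],
) -> list[tuple[str, str]]:
    """Mutual best hits between two id sets, given a->b oriented hits."""
    fwd: dict[str, list[SimilarityHit]] = {}
    rev: dict[str, list[SimilarityHit]] = {}
    a_set, b_set = set(a_ids), set(b_ids)
    for h in hits:
        if h.query_id in a_set and h.subject_id in b_set:
            fwd.setdefault(h.query_id, []).append(h)
            rev.setdefault(h.subject_id, []).append(h.swapped())
    out: list[tuple[str, str]] = []
    for a in sorted(a_set):
        b = _best_partner(a, fwd)
        if b is not None and _best_partner(b, rev) == a:
            out.append((a, b))
    return out


def synteny_aware_bbh(
    genome_a: Genome,
    genome_b: Genome,
    cds_map: Mapping[str, CDS],
    engine: AlignmentEngine,
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
    gap_limit: int = DEFAULT_GAP_LIMIT,
    strict_synteny: bool = False,
) -> SpeciesOrthologResult:
    """Call species-level orthologs between two conspecific genomes.

    The result is a partial matching (each CDS in at most one pair); every
    emitted pair satisfies the identity and coverage thresholds.  The
    computation is symmetric: the genome pair is canonicalised internally,
    so swapping the arguments yields the same pair set.
    """
    if genome_a.genome_id == genome_b.genome_id:
        raise UsageError("species orthologs need two distinct genomes")
    if not (0 < min_identity <= 100) or not (0 < min_coverage <= 100):
        raise UsageError("thresholds must lie in (0, 100]")
    if genome_a.genome_id > genome_b.genome_id:
        genome_a, genome_b = genome_b, genome_a

    cdss_a = [cds_map[c] for c in genome_a.cds_ids]
    cdss_b = [cds_map[c] for c in genome_b.cds_ids]
    hits = engine.all_vs_all(cdss_a, cdss_b, min_identity, min_coverage)
    hit_by_key: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = hit_by_key.get(key)
        if prev is None or h.score > prev.score:
            hit_by_key[key] = h

    if strict_synteny:
        # literal behaviour: only genuinely coordinate-backed blocks count
        anchor_hits = [
            h
            for h in hits
            if cds_map[h.query_id].has_coordinates
            and cds_map[h.subject_id].has_coordinates
        ]
    else:
        anchor_hits = hits
    blocks = syntenic_blocks(anchor_hits, dict(cds_map), gap_limit=gap_limit)

    paired_a: set[str] = set()
    paired_b: set[str] = set()
    accepted: list[tuple[str, str]] = []

    for block in blocks:
        block_a = [a for a, _ in block.anchors]
        block_b = [b for _, b in block.anchors]
        block_hits = [hit_by_key[(a, b)] for a, b in block.anchors]
        for a, b in _bbh(block_a, block_b, block_hits):
            if a not in paired_a and b not in paired_b:
                accepted.append((a, b))
                paired_a.add(a)
                paired_b.add(b)

    if not strict_synteny:
        rest_hits = [
            h
            for h in hits
            if h.query_id not in paired_a and h.subject_id not in paired_b
        ]
        rest_a = [c.cds_id for c in cdss_a if c.cds_id not in paired_a]
        rest_b = [c.cds_id for c in cdss_b if c.cds_id not in paired_b]
        for a, b in _bbh(rest_a, rest_b, rest_hits):
            accepted.append((a, b))
            paired_a.add(a)
            paired_b.add(b)

    pairs = [OrthologPair.make(a, b, "species", "species_bbh") for a, b in accepted]
    pairs.sort(key=lambda p: p.key)
    pair_hits = {
        OrthologPair.make(a, b, "species", "species_bbh").key: hit_by_key[(a, b)]
        for a, b in accepted
    }
    return SpeciesOrthologResult(pairs=pairs, hits=pair_hits)
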