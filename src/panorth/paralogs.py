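"""Within-genome paralog detection: all-vs-all local alignment of a
genome's CDSs with no identity/coverage thresholds — the aligner's
score floor is the only (implicit) cutoff — keeping the best-scoring
alignment per unordered pair."""

from __future__ import annotations

from typing import Mapping

from .align import AlignmentEngine
from .model import CDS, Genome, ParalogPair, UsageError


def compute_paralogs(
    genome: Genome,
    cds_map: Mapping[str, CDS],
    engine: AlignmentEngine,
) -> list[ParalogPair]:
    """All unordered CDS pairs of a genome whose optimal local alignment
    clears the engine's score floor, best-scoring alignment per pair."""
    if not genome.cds_ids:
        raise UsageError(f"genome {genome.genome_id!r} has no CDSs")
    cdss = [cds_map[cid] for cid in genome.cds_ids]
    if len(cdss) < 2:
        return []
    hits = engine.all_vs_all(cdss, cdss)
    pairs = [ParalogPair.make(h.query_id, h.subject_id, h) for h in hits]
    pairs.sort(key=lambda p: p.key)
    return pairs


def paralog_table_rows(genome: Genome, pairs: list[ParalogPair]) -> list[dict]:
    """Rows for the paralog TSV: genome, ids, identity, coverage, score."""
    return [
        {
            "genome_id": genome.genome_id,
            "cds_a": p.cds_a,
            "cds_b": p.cds_b,
            "identity": round(p.hit.identity, 3),
            "coverage": round(p.hit.coverage, 3),
            "score": p.hit.score,
        }
        for p in pairs
    ]
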