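"""Global ortholog groups, the genome-occurrence spectrum, core-genome
extraction and the six-frame rescue search for annotation gaps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .align import AlignmentEngine, six_frame_translate
from .model import CDS, Genome, OrthologPair, SimilarityHit, UsageError
from .pangenome import single_linkage


@dataclass
class OrthologGroupGlobal:
    """A single-linkage group over all levels' ortholog pairs."""

    group_id: str
    members: list[str]
    occurrence_count: int
    occurrence_fraction: float


def cluster_all_pairs(
    all_pairs: Iterable[OrthologPair],
    cds_ids: Iterable[str],
    genome_of: Mapping[str, str],
    n_genomes: int,
) -> tuple[list[OrthologGroupGlobal], list[str]]:
    """Single-linkage groups over the union of all levels' pairs.

    Every group has at least two members; CDSs in no pair are returned
    separately as orphans.  Each CDS belongs to at most one group.
    """
    ids = sorted(set(cds_ids))
    edges = [(p.cds_a, p.cds_b) for p in all_pairs]
    groups: list[OrthologGroupGlobal] = []
    orphans: list[str] = []
    for i, comp in enumerate(single_linkage(ids, edges)):
        if len(comp) == 1:
            orphans.append(comp[0])
            continue
        genomes = {genome_of[c] for c in comp}
        groups.append(
            OrthologGroupGlobal(
                group_id=f"OG{i:06d}",
                members=list(comp),
                occurrence_count=len(genomes),
                occurrence_fraction=len(genomes) / n_genomes,
            )
        )
    return groups, orphans


def occurrence_spectrum(
    groups: Sequence[OrthologGroupGlobal],
    orphans: Sequence[str],
    n_bins: int = 10,
) -> list[float]:
    """Fraction of all CDSs whose group occupies each occurrence bin.

    Bin ``i`` covers occurrence fractions in ``(i/n_bins, (i+1)/n_bins]``;
    a group's CDSs all land in its bin.  The bin masses plus the orphan
    fraction sum to one.
    """
    total = sum(len(g.members) for g in groups) + len(orphans)
    if total == 0:
        raise UsageError("no CDSs to bin")
    bins = [0.0] * n_bins
    for g in groups:
        idx = min(n_bins - 1, int((g.occurrence_fraction * n_bins) - 1e-12))
        bins[idx] += len(g.members) / total
    return bins


def core_genome(
    groups: Sequence[OrthologGroupGlobal],
    genomes: Sequence[Genome],
    genome_of: Mapping[str, str],
    threshold: float = 0.90,
) -> list[tuple[OrthologGroupGlobal, list[str]]]:
    """Groups present in at least ``threshold`` of the genomes (inclusive),
    each with the list of genomes lacking any member."""
    if not (0 < threshold <= 1):
        raise UsageError("threshold must lie in (0, 1]")
    all_ids = [g.genome_id for g in genomes]
    out = []
    for grp in groups:
        if grp.occurrence_fraction >= threshold:
            present = {genome_of[c] for c in grp.members}
            missing = sorted(set(all_ids) - present)
            out.append((grp, missing))
    return out


@dataclass
class RescueHit:
    """Best six-frame hit for one query protein against one genome."""

    query_id: str
    contig: str
    frame: int  # 0-2 forward, 3-5 reverse
    hit: Optional[SimilarityHit]
    passed: bool


def rescue_search(
    contigs: Mapping[str, str],
    query_proteins: Sequence[CDS],
    engine: AlignmentEngine,
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> list[RescueHit]:
    """Align each query protein against all six frame translations of every
    contig; report the best hit per query with a pass/fail verdict.

    Frames are aligned independently (no frameshift stitching), so a CDS
    straddling a frameshift will not reach full coverage in any one frame.
    """
    if not contigs:
        raise UsageError("rescue search needs at least one contig")
    frames_by_contig = {
        name: six_frame_translate(seq) for name, seq in sorted(contigs.items())
    }
    out: list[RescueHit] = []
    for query in query_proteins:
        best: Optional[RescueHit] = None
        for contig, frames in frames_by_contig.items():
            for idx, frame_seq in enumerate(frames):
                if len(frame_seq.replace("*", "")) == 0:
                    continue
                hit = engine.local_align(
                    query.protein_seq, frame_seq, query.cds_id, f"{contig}|frame{idx}"
                )
                if hit is None:
                    continue
                if best is None or hit.score > best.hit.score:
                    best = RescueHit(query.cds_id, contig, idx, hit, False)
        if best is None:
            out.append(RescueHit(query.cds_id, "", -1, None, False))
        else:
            best.passed = (
                best.hit.identity >= min_identity and best.hit.coverage >= min_coverage
            )
            out.append(best)
    return out
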