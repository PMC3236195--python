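"""Pairwise protein similarity, all-vs-all search, syntenic-block detection
and six-frame translation.

All CDS-vs-CDS comparisons are exact affine-gap Smith-Waterman local
alignments in protein space (BLOSUM62, gap of length ``g`` costs
``open + g * extend`` — the BLAST convention), computed with Biopython's C
aligner.  Identity is the fraction of identical column pairs over aligned
columns (gap columns included); coverage is the fraction of the *shorter*
sequence's residues inside the local alignment.  Expectation values are
Karlin-Altschul estimates ``E = K * m * n * exp(-lambda * S)`` with the
published gapped BLOSUM62 11/1 parameters.

An adapter producing ``SimilarityHit`` tuples from an external search tool
may substitute this engine wherever a ``hits_between``-shaped callable is
accepted, as long as the hit invariants hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .model import CDS, IntegrityError, PanorthError, SimilarityHit, UsageError


class InputError(PanorthError):
    """A sequence contains characters outside the scoring alphabet."""


# Published Karlin-Altschul parameters for gapped BLOSUM62, open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

#: -log10(e-value) is capped here; identical long sequences underflow E.
MAX_NEG_LOG10_EVALUE = 300.0


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of length
    g costs ``gap_open + g * gap_extend``.  ``score_floor`` is the minimum
    local-alignment score below which no hit is reported — the engine's
    implicit homology cutoff (the analogue of a seed-and-extend tool's
    minimum cluster size).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    score_floor: float = 40.0
    ka_lambda: float = KA_LAMBDA
    ka_k: float = KA_K


@dataclass(frozen=True)
class SyntenicBlock:
    """A chain of collinear, consistently oriented anchor pairs."""

    contig_a: str
    contig_b: str
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    anchors: tuple[tuple[str, str], ...]
    length: int
    orientation: str  # "same" | "inverted"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise IntegrityError("syntenic block with non-positive length")


def strip_stop(seq: str) -> str:
    """Remove a trailing stop symbol before alignment."""
    return seq[:-1] if seq.endswith("*") else seq


def estimate_evalue(
    score: float,
    len_q: int,
    len_s: int,
    search_space: Optional[float] = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> float:
    """Karlin-Altschul expectation value for a local alignment score.

    ``search_space`` defaults to the product of the two sequence lengths;
    pass the database residue product for database-wide statistics.
    """
    if len_q < 1 or len_s < 1:
        raise UsageError("sequence lengths must be >= 1")
    if not math.isfinite(score):
        raise UsageError("score must be finite")
    if search_space is None:
        search_space = float(len_q) * float(len_s)
    return scheme.ka_k * search_space * math.exp(-scheme.ka_lambda * score)


class AlignmentEngine:
    """Exact local protein aligner with hit bookkeeping.

    ``n_comparisons`` counts every pairwise score computation performed —
    the quantity the divide-and-conquer design minimises.
    """

    def __init__(self, scheme: ScoringScheme = ScoringScheme()):
        self.scheme = scheme
        self.n_comparisons = 0
        matrix = substitution_matrices.load(scheme.matrix)
        self._alphabet = set(str(matrix.alphabet))
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = matrix
        # Biopython charges open_gap_score for the first gap residue; the
        # BLAST convention charges open + extend for it.
        self._aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        self._aligner.extend_gap_score = -scheme.gap_extend

    # -- single pair ---------------------------------------------------

    def _check(self, seq: str) -> str:
        seq = strip_stop(seq.upper())
        if not seq:
            raise InputError("empty sequence after stop stripping")
        bad = set(seq) - self._alphabet
        if bad:
            raise InputError(f"illegal residue character(s) {sorted(bad)}")
        return seq

    def local_align(
        self,
        seq_a: str,
        seq_b: str,
        query_id: str = "query",
        subject_id: str = "subject",
        search_space: Optional[float] = None,
    ) -> Optional[SimilarityHit]:
        """Optimal local alignment of two protein sequences.

        Returns ``None`` when the optimal score is below the scheme's
        floor.  Identity, coverage and score are invariant under argument
        swap (the pair is canonicalised internally before traceback).
        """
        a = self._check(seq_a)
        b = self._check(seq_b)
        self.n_comparisons += 1
        # canonical internal order makes the traceback, and hence identity
        # and coverage, symmetric in the two arguments
        x, y = (a, b) if (len(a), a) <= (len(b), b) else (b, a)
        score = self._aligner.score(x, y)
        if score < self.scheme.score_floor:
            return None
        aln = self._aligner.align(x, y)[0]
        x_blocks, y_blocks = aln.aligned
        matched = int(sum(e - s for s, e in x_blocks))
        span_x = int(x_blocks[-1][1] - x_blocks[0][0])
        span_y = int(y_blocks[-1][1] - y_blocks[0][0])
        columns = span_x + span_y - matched
        identical = 0
        for (xs, xe), (ys, ye) in zip(x_blocks, y_blocks):
            identical += sum(1 for p, q in zip(x[xs:xe], y[ys:ye]) if p == q)
        shorter = min(len(a), len(b))
        span_shorter = span_x if len(x) <= len(y) else span_y
        identity = 100.0 * float(identical) / columns
        coverage = 100.0 * span_shorter / shorter
        evalue = estimate_evalue(score, len(a), len(b), search_space, self.scheme)
        return SimilarityHit(
            query_id=query_id,
            subject_id=subject_id,
            identity=identity,
            coverage=coverage,
            score=float(score),
            evalue=evalue,
            aligned_length=columns,
        )

    # -- collections ---------------------------------------------------

    def all_vs_all(
        self,
        set_a: Sequence[CDS],
        set_b: Sequence[CDS],
        min_identity: float = 0.0,
        min_coverage: float = 0.0,
    ) -> list[SimilarityHit]:
        """Every pair between (or within) two CDS collections that clears
        the score floor and both percentage thresholds.

        When the same collection is passed twice, each unordered pair is
        reported once (query = lexicographically smaller id) and self-hits
        are excluded.
        """
        if not set_a or not set_b:
            raise UsageError("all_vs_all requires non-empty CDS collections")
        same = set_a is set_b or [c.cds_id for c in set_a] == [c.cds_id for c in set_b]
        hits: list[SimilarityHit] = []
        for i, ca in enumerate(set_a):
            targets = set_b[i + 1 :] if same else set_b
            for cb in targets:
                hit = self.local_align(
                    ca.protein_seq, cb.protein_seq, ca.cds_id, cb.cds_id
                )
                if hit is None:
                    continue
                if hit.identity < min_identity or hit.coverage < min_coverage:
                    continue
                if same and hit.query_id > hit.subject_id:
                    hit = hit.swapped()
                hits.append(hit)
        return hits


# ---------------------------------------------------------------------------
# Syntenic blocks
# ---------------------------------------------------------------------------

#: Default maximum nucleotide gap between consecutive anchors in a chain.
DEFAULT_GAP_LIMIT = 20_000


def _anchor_orientation(ca: CDS, cb: CDS) -> str:
    sa = ca.strand or "+"
    sb = cb.strand or "+"
    return "same" if sa == sb else "inverted"


def syntenic_blocks(
    anchor_hits: Iterable[SimilarityHit],
    cds_map: dict[str, CDS],
    gap_limit: int = DEFAULT_GAP_LIMIT,
) -> list[SyntenicBlock]:
    """Chain anchor hits into collinear blocks, longest first.

    Anchors whose CDSs carry coordinates are chained per (contig pair,
    orientation): consecutive anchors (by genome-A start) join a chain when
    both genomes advance in the chain's direction with inter-anchor gaps at
    most ``gap_limit``.  Anchors without coordinates fall back to one block
    per contig pair, ranked by anchor count.  Each anchor lands in exactly
    one block.  Ordering is deterministic: length descending, then
    (contig_a, contig_b, start_a).
    """
    with_coords: dict[tuple[str, str, str], list[SimilarityHit]] = {}
    without: dict[tuple[str, str], list[SimilarityHit]] = {}
    for hit in anchor_hits:
        ca, cb = cds_map[hit.query_id], cds_map[hit.subject_id]
        if ca.has_coordinates and cb.has_coordinates:
            key = (ca.contig, cb.contig, _anchor_orientation(ca, cb))
            with_coords.setdefault(key, []).append(hit)
        else:
            key2 = (ca.contig or "", cb.contig or "")
            without.setdefault(key2, []).append(hit)

    blocks: list[SyntenicBlock] = []
    for (contig_a, contig_b, orient), hits in with_coords.items():
        hits.sort(
            key=lambda h: (cds_map[h.query_id].start, cds_map[h.subject_id].start)
        )
        chain: list[SimilarityHit] = []

        def flush() -> None:
            if not chain:
                return
            astarts = [cds_map[h.query_id].start for h in chain]
            aends = [cds_map[h.query_id].end for h in chain]
            bstarts = [cds_map[h.subject_id].start for h in chain]
            bends = [cds_map[h.subject_id].end for h in chain]
            sa, ea = min(astarts), max(aends)
            sb, eb = min(bstarts), max(bends)
            blocks.append(
                SyntenicBlock(
                    contig_a=contig_a,
                    contig_b=contig_b,
                    start_a=sa,
                    end_a=ea,
                    start_b=sb,
                    end_b=eb,
                    anchors=tuple((h.query_id, h.subject_id) for h in chain),
                    length=max(ea - sa + 1, eb - sb + 1),
                    orientation=orient,
                )
            )

        for hit in hits:
            if not chain:
                chain.append(hit)
                continue
            prev = chain[-1]
            pa, na = cds_map[prev.query_id], cds_map[hit.query_id]
            pb, nb = cds_map[prev.subject_id], cds_map[hit.subject_id]
            gap_a = na.start - pa.end
            if orient == "same":
                forward = nb.start > pb.start
                gap_b = nb.start - pb.end
            else:
                forward = nb.start < pb.start
                gap_b = pb.start - nb.end
            if forward and gap_a <= gap_limit and gap_b <= gap_limit:
                chain.append(hit)
            else:
                flush()
                chain = [hit]
        flush()

    for (contig_a, contig_b), hits in sorted(without.items()):
        blocks.append(
            SyntenicBlock(
                contig_a=contig_a,
                contig_b=contig_b,
                start_a=1,
                end_a=len(hits),
                start_b=1,
                end_b=len(hits),
                anchors=tuple((h.query_id, h.subject_id) for h in hits),
                length=len(hits),
                orientation="same",
            )
        )

    blocks.sort(key=lambda b: (-b.length, b.contig_a, b.contig_b, b.start_a))
    return blocks


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------

_NT = set("ACGTN")


def six_frame_translate(nucleotide_seq: str) -> list[str]:
    """Translate all six reading frames (standard code).

    Returns three forward-frame and three reverse-complement-frame
    translations, in that order; ambiguous codons translate to ``X`` and
    stops to ``*``.
    """
    seq = nucleotide_seq.upper()
    bad = set(seq) - _NT
    if bad:
        raise InputError(f"illegal nucleotide character(s) {sorted(bad)}")
    frames: list[str] = []
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for offset in range(3):
            sub = strand_seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(Seq(sub).translate()))
    return frames
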