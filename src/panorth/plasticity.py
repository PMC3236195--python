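"""Pan-genome openness and genomic fluidity.

Openness follows the new-gene discovery curve: add a species' genomes in
random order and count, for the N-th genome, the CDSs with no ortholog
(70/70 identity/coverage) in any earlier genome and no near-identical
(90/90) duplicate already counted new within the incoming genome.  The
per-N medians over permutations are fitted with the sub-linear power law
``n = kappa * N**(-alpha)`` by ordinary least squares in log-log space
(exactly what a spreadsheet "power trendline" computes); species with
``alpha > 1`` have closed pan-genomes, ``alpha <= 1`` open ones.

Genomic fluidity is a gene-content dissimilarity: for a genome pair the
ratio of summed unique-CDS counts to summed total CDS counts, where a CDS
is shared when it has a 70/70 hit in the partner genome; the species value
is the median over all pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .align import AlignmentEngine
from .model import CDS, Genome, UsageError


@dataclass
class OpennessFit:
    """Fitted power-law parameters over the median new-CDS curve."""

    species: str
    n_genomes_axis: list[int]  # N = 2..G
    median_new: list[float]  # median n(N) over permutations
    kappa: float
    alpha: float
    r_squared: float
    classification: str  # "open" | "closed"


@dataclass
class FluidityPairRecord:
    genome_k: str
    genome_l: str
    unique_k: int
    unique_l: int
    total_k: int
    total_l: int

    @property
    def ratio(self) -> float:
        return (self.unique_k + self.unique_l) / (self.total_k + self.total_l)


@dataclass
class FluidityEstimate:
    species: str
    pair_records: list[FluidityPairRecord]
    median: float


def _pairwise_share_maps(
    genomes: Sequence[Genome],
    cds_map: Mapping[str, CDS],
    engine: AlignmentEngine,
    cut: tuple[float, float],
) -> dict[tuple[str, str], set[str]]:
    """For each ordered genome pair (g, h): the CDSs of g with a hit in h
    at the given identity/coverage cut."""
    shares: dict[tuple[str, str], set[str]] = {}
    for i, g in enumerate(genomes):
        for h in genomes[i + 1 :]:
            hits = engine.all_vs_all(
                [cds_map[c] for c in g.cds_ids],
                [cds_map[c] for c in h.cds_ids],
                min_identity=cut[0],
                min_coverage=cut[1],
            )
            fwd = {hit.query_id for hit in hits}
            rev = {hit.subject_id for hit in hits}
            shares[(g.genome_id, h.genome_id)] = fwd
            shares[(h.genome_id, g.genome_id)] = rev
    return shares


def _within_duplicate_map(
    genome: Genome,
    cds_map: Mapping[str, CDS],
    engine: AlignmentEngine,
    cut: tuple[float, float],
) -> dict[str, set[str]]:
    """Near-identical duplicate partners within one genome at the cut."""
    cdss = [cds_map[c] for c in genome.cds_ids]
    dup: dict[str, set[str]] = {c.cds_id: set() for c in cdss}
    if len(cdss) < 2:
        return dup
    for hit in engine.all_vs_all(cdss, cdss, min_identity=cut[0], min_coverage=cut[1]):
        dup[hit.query_id].add(hit.subject_id)
        dup[hit.subject_id].add(hit.query_id)
    return dup


def new_cds_series(
    genomes: Sequence[Genome],
    cds_map: Mapping[str, CDS],
    engine: AlignmentEngine,
    ortholog_cut: tuple[float, float] = (70.0, 70.0),
    paralog_cut: tuple[float, float] = (90.0, 90.0),
    n_permutations: int = 100,
    seed: int = 0,
    dedup_within_incoming: bool = True,
) -> tuple[list[int], list[float]]:
    """Median new-CDS counts n(N) for N = 2..G over random genome orders.

    All pairwise hit sets are computed once; each permutation is then a
    cheap set computation.  A new CDS has no ortholog-cut hit in any earlier
    genome; with ``dedup_within_incoming`` a paralog-cut duplicate of a CDS
    already counted new in the same incoming genome is not counted again
    (so a novel duplicated gene counts once).
    """
    if len(genomes) < 2:
        raise UsageError("new-CDS series needs at least two genomes")
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    shares = _pairwise_share_maps(genomes, cds_map, engine, ortholog_cut)
    dups = (
        {g.genome_id: _within_duplicate_map(g, cds_map, engine, paralog_cut) for g in genomes}
        if dedup_within_incoming
        else None
    )
    rng = np.random.default_rng(seed)
    g_count = len(genomes)
    counts = np.zeros((n_permutations, g_count - 1))
    for p in range(n_permutations):
        order = rng.permutation(g_count)
        for pos in range(1, g_count):
            incoming = genomes[order[pos]]
            earlier = [genomes[order[j]].genome_id for j in range(pos)]
            new_ids: list[str] = []
            new_set: set[str] = set()
            for cid in incoming.cds_ids:
                if any(cid in shares[(incoming.genome_id, e)] for e in earlier):
                    continue
                if dups is not None and dups[incoming.genome_id][cid] & new_set:
                    continue
                new_ids.append(cid)
                new_set.add(cid)
            counts[p, pos - 1] = len(new_ids)
    medians = np.median(counts, axis=0)
    return list(range(2, g_count + 1)), [float(x) for x in medians]


def fit_power_law(
    n_values: Sequence[int],
    new_counts: Sequence[float],
    species: str = "",
) -> OpennessFit:
    """Fit ``n = kappa * N**(-alpha)`` by OLS on (log N, log n).

    Points with ``n == 0`` are excluded from the regression.  If every
    point is zero the species is trivially closed and the fit is flagged
    degenerate (``alpha = inf``, ``kappa = 0``).
    """
    pts = [(N, n) for N, n in zip(n_values, new_counts) if n > 0]
    if not pts:
        return OpennessFit(
            species=species,
            n_genomes_axis=list(n_values),
            median_new=list(new_counts),
            kappa=0.0,
            alpha=math.inf,
            r_squared=1.0,
            classification="closed",
        )
    if len(pts) < 2:
        raise UsageError("power-law fit needs at least two non-zero points")
    log_n = np.log([p[0] for p in pts])
    log_y = np.log([p[1] for p in pts])
    slope, intercept = np.polyfit(log_n, log_y, 1)
    pred = slope * log_n + intercept
    ss_res = float(np.sum((log_y - pred) ** 2))
    ss_tot = float(np.sum((log_y - log_y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    alpha = -float(slope)
    kappa = float(np.exp(intercept))
    return OpennessFit(
        species=species,
        n_genomes_axis=list(n_values),
        median_new=list(new_counts),
        kappa=kappa,
        alpha=alpha,
        r_squared=r2,
        # tiny tolerance absorbs regression round-off at the boundary
        classification="closed" if alpha > 1 + 1e-9 else "open",
    )


def genomic_fluidity(
    genomes: Sequence[Genome],
    cds_map: Mapping[str, CDS],
    engine: AlignmentEngine,
    share_cut: tuple[float, float] = (70.0, 70.0),
    species: str = "",
) -> FluidityEstimate:
    """Median over genome pairs of (unique_k + unique_l) / (M_k + M_l).

    A CDS is shared when it has a hit at the share cut in the partner
    genome; fluidity 0.2 means 20% of the CDSs in a genome pair are unique
    to their host genome while 80% are shared.
    """
    if len(genomes) < 2:
        raise UsageError("fluidity needs at least two genomes")
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    shares = _pairwise_share_maps(genomes, cds_map, engine, share_cut)
    records: list[FluidityPairRecord] = []
    for i, g in enumerate(genomes):
        for h in genomes[i + 1 :]:
            shared_g = shares[(g.genome_id, h.genome_id)]
            shared_h = shares[(h.genome_id, g.genome_id)]
            records.append(
                FluidityPairRecord(
                    genome_k=g.genome_id,
                    genome_l=h.genome_id,
                    unique_k=len(g.cds_ids) - len(shared_g),
                    unique_l=len(h.cds_ids) - len(shared_h),
                    total_k=len(g.cds_ids),
                    total_l=len(h.cds_ids),
                )
            )
    median = float(np.median([r.ratio for r in records]))
    return FluidityEstimate(species=species, pair_records=records, median=median)
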