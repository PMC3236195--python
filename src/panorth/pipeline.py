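"""End-to-end orchestration: paralogs -> species orthologs -> species
pan-genomes -> rank climb (genus..domain) -> analytics-ready store."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .align import AlignmentEngine
from .level_orthologs import ArtifactStore, LevelParams, run_level
from .model import CDS, Genome, OrthologPair, ParalogPair, SimilarityHit, TaxonomyTree
from .pangenome import build_species_pangenome
from .paralogs import compute_paralogs
from .species_orthologs import synteny_aware_bbh

CLIMB_RANKS = ("genus", "family", "order", "class", "phylum", "domain")


@dataclass
class PipelineResult:
    store: ArtifactStore
    paralogs: dict[str, list[ParalogPair]]  # genome_id -> pairs
    species_hits: dict[tuple[str, str], SimilarityHit]  # pair key -> hit
    n_species_comparisons: int = 0

    @property
    def all_pairs(self) -> list[OrthologPair]:
        return list(self.store.pairs)


def run_pipeline(
    genomes: Sequence[Genome],
    taxonomy: TaxonomyTree,
    cds_map: Mapping[str, CDS],
    engine: Optional[AlignmentEngine] = None,
    level_params: Optional[Mapping[str, LevelParams]] = None,
    strict_synteny: bool = False,
) -> PipelineResult:
    """Run the full taxonomic climb over a genome collection."""
    engine = engine or AlignmentEngine()
    store = ArtifactStore()
    genome_by_id = {g.genome_id: g for g in genomes}
    paralogs_by_genome: dict[str, list[ParalogPair]] = {}
    species_hits: dict[tuple[str, str], SimilarityHit] = {}

    start = engine.n_comparisons
    for species in taxonomy.taxa_at_rank("species"):
        gids = taxonomy.genomes_under(species)
        sp_genomes = [genome_by_id[g] for g in gids]
        sp_paralogs: list[ParalogPair] = []
        for g in sp_genomes:
            pairs = compute_paralogs(g, cds_map, engine)
            paralogs_by_genome[g.genome_id] = pairs
            sp_paralogs.extend(pairs)
        sp_orthologs: list[tuple[OrthologPair, SimilarityHit]] = []
        for ga, gb in itertools.combinations(sp_genomes, 2):
            res = synteny_aware_bbh(
                ga, gb, cds_map, engine, strict_synteny=strict_synteny
            )
            for p in res.pairs:
                sp_orthologs.append((p, res.hit_for(p)))
                species_hits[p.key] = res.hit_for(p)
        pangenome, _groups = build_species_pangenome(
            species, sp_genomes, cds_map, sp_paralogs, sp_orthologs
        )
        store.pangenomes[species] = pangenome
        store.pairs.extend(p for p, _h in sp_orthologs)
    n_species_comp = engine.n_comparisons - start

    for rank in CLIMB_RANKS:
        params = (level_params or {}).get(rank)
        run_level(rank, taxonomy, store, cds_map, engine, params)

    return PipelineResult(
        store=store,
        paralogs=paralogs_by_genome,
        species_hits=species_hits,
        n_species_comparisons=n_species_comp,
    )
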