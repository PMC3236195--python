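"""Synthetic clade generation with known ortholog/paralog ground truth.

A random ancestral proteome descends a taxonomy tree; every branch applies
uniform residue substitution at a fixed per-site divergence, gene loss,
gene gain (fresh random genes) and gene duplication.  Every CDS keeps its
ancestral-gene label, so true ortholog pairs (same label, different
genomes), true paralog pairs (same label, same genome) and per-gene
universality are known exactly.  Genes are laid along a single contig in
label order with fixed spacing, so conspecific genomes are syntenic by
construction (a shuffle switch breaks synteny for testing).

Substitutions are uniform over the 19 alternative residues — no
substitution-matrix realism — which keeps expected sequence identity
analytically predictable: two genomes separated by branches with
divergences d_1..d_m agree at a site with probability ~ prod(1 - d_i)
(plus a small back-mutation term).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from scipy.special import comb

from .align import AlignmentEngine
from .model import CDS, Genome, RANKS, TaxonomyTree, UsageError

AA = "ACDEFGHIKLMNPQRSTVWY"

#: ranks between domain and species, in descending order
_MID_RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class CladeSpec:
    """Shape and evolutionary parameters of a simulated clade.

    ``branching[rank]`` is the number of rank children under each parent
    node (ranks phylum..species); ``genomes_per_species`` closes the tree.
    Rates are per branch; ``divergence`` is the per-site substitution
    fraction.
    """

    branching: dict = field(
        default_factory=lambda: {"genus": 2, "species": 2}
    )
    genomes_per_species: int = 2
    n_genes: int = 200
    divergence: float = 0.02
    gain_rate: float = 0.05
    loss_rate: float = 0.05
    dup_rate: float = 0.0
    length_range: tuple[int, int] = (50, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "gain_rate", "loss_rate", "dup_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise UsageError(f"{name} must lie in [0, 1], got {v}")
        if self.seed is None:
            raise UsageError("a seed is mandatory")

    def children_at(self, rank: str) -> int:
        return int(self.branching.get(rank, 1))


@dataclass
class GroundTruth:
    """Ancestral-gene labels and the pair sets they imply."""

    label_of: dict[str, str]  # cds_id -> ancestral gene label
    genome_of: dict[str, str]
    universal_labels: set[str]  # labels present in every genome

    def ortholog_pairs(self) -> set[tuple[str, str]]:
        """Same label, different genomes (canonically ordered)."""
        by_label: dict[str, list[str]] = {}
        for cid, lab in self.label_of.items():
            by_label.setdefault(lab, []).append(cid)
        out: set[tuple[str, str]] = set()
        for members in by_label.values():
            members.sort()
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if self.genome_of[a] != self.genome_of[b]:
                        out.add((a, b))
        return out

    def paralog_pairs(self) -> set[tuple[str, str]]:
        """Same label, same genome (duplication descendants)."""
        by_label: dict[str, list[str]] = {}
        for cid, lab in self.label_of.items():
            by_label.setdefault(lab, []).append(cid)
        out: set[tuple[str, str]] = set()
        for members in by_label.values():
            members.sort()
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if self.genome_of[a] == self.genome_of[b]:
                        out.add((a, b))
        return out

    def ortholog_pairs_at_rank(
        self, rank: str, lineages: dict[str, dict[str, str]]
    ) -> set[tuple[str, str]]:
        """Truth pairs whose two genomes first meet at the given rank."""
        idx = RANKS.index(rank)
        out = set()
        for a, b in self.ortholog_pairs():
            la, lb = lineages[self.genome_of[a]], lineages[self.genome_of[b]]
            lca = next(r for r in RANKS if la[r] == lb[r])
            if RANKS.index(lca) == idx:
                out.add((a, b))
        return out


@dataclass
class CladeResult:
    genomes: list[Genome]
    cds_map: dict[str, CDS]
    taxonomy: TaxonomyTree
    truth: GroundTruth
    spec: CladeSpec


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=length))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0:
        return seq
    chars = list(seq)
    mask = rng.random(len(chars)) < divergence
    for i in np.nonzero(mask)[0]:
        old = chars[i]
        choices = AA.replace(old, "")
        chars[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def _evolve_branch(
    genes: list[tuple[str, str]],
    spec: CladeSpec,
    rng: np.random.Generator,
    fresh_label: "list[int]",
) -> list[tuple[str, str]]:
    """Apply one branch of evolution: substitutions, duplication, loss, gain."""
    out: list[tuple[str, str]] = []
    for label, seq in genes:
        mutated = _mutate(seq, spec.divergence, rng)
        out.append((label, mutated))
        if spec.dup_rate and rng.random() < spec.dup_rate:
            out.append((label, _mutate(mutated, spec.divergence, rng)))
    if spec.loss_rate:
        keep_mask = rng.random(len(out)) >= spec.loss_rate
        kept = [g for g, k in zip(out, keep_mask) if k]
        out = kept if kept else out[:1]
    if spec.gain_rate:
        n_gain = int(rng.binomial(max(len(out), 1), spec.gain_rate))
        for _ in range(n_gain):
            fresh_label[0] += 1
            out.append(
                (f"gene{fresh_label[0]:05d}", _random_protein(rng, *spec.length_range))
            )
    return out


def simulate_clade(spec: CladeSpec, outdir: Optional[str] = None) -> CladeResult:
    """Simulate a clade of genomes under the spec; deterministic per seed.

    With ``outdir`` the FASTA/coordinate/manifest/truth files are written
    in the formats the package reads back.
    """
    expected_within_species_identity = (1.0 - spec.divergence) ** 2
    if expected_within_species_identity < 0.70:
        warnings.warn(
            "per-branch divergence so high that expected within-species "
            f"identity ({expected_within_species_identity:.2f}) is below the "
            "species ortholog threshold",
            stacklevel=2,
        )

    rng = np.random.default_rng(spec.seed)
    root_genes = [
        (f"gene{i:05d}", _random_protein(rng, *spec.length_range))
        for i in range(spec.n_genes)
    ]
    fresh_label = [spec.n_genes - 1]

    genomes: list[Genome] = []
    cds_map: dict[str, CDS] = {}
    label_of: dict[str, str] = {}
    genome_of: dict[str, str] = {}

    def descend(
        rank_idx: int, genes: list[tuple[str, str]], lineage: dict[str, str], tag: str
    ) -> None:
        # rank_idx indexes RANKS from the top: RANKS[::-1]
        top_down = RANKS[::-1]
        if rank_idx == len(top_down):  # below species: emit genomes
            for gi in range(spec.genomes_per_species):
                genome_id = f"{tag}_g{gi + 1}"
                genome_genes = _evolve_branch(genes, spec, rng, fresh_label)
                _emit_genome(genome_id, dict(lineage), genome_genes)
            return
        rank = top_down[rank_idx]
        n_children = spec.children_at(rank) if rank != "domain" else 1
        for ci in range(n_children):
            child_tag = f"{tag}{rank[0].upper()}{ci + 1}"
            child_lineage = dict(lineage)
            child_lineage[rank] = child_tag
            child_genes = (
                genes if rank == "domain" else _evolve_branch(genes, spec, rng, fresh_label)
            )
            descend(rank_idx + 1, child_genes, child_lineage, child_tag)

    def _emit_genome(
        genome_id: str, lineage: dict[str, str], genes: list[tuple[str, str]]
    ) -> None:
        copy_counter: dict[str, int] = {}
        pos = 1
        cds_ids = []
        ordered = sorted(genes, key=lambda g: g[0])
        for label, seq in ordered:
            copy_counter[label] = copy_counter.get(label, 0) + 1
            cds_id = f"{genome_id}|{label}.{copy_counter[label]}"
            nt_len = 3 * len(seq) + 3
            cds = CDS(
                cds_id=cds_id,
                genome_id=genome_id,
                protein_seq=seq,
                contig=f"{genome_id}_c1",
                start=pos,
                end=pos + nt_len - 1,
                strand="+",
            )
            pos += nt_len + 100
            cds_map[cds_id] = cds
            cds_ids.append(cds_id)
            label_of[cds_id] = label
            genome_of[cds_id] = genome_id
        genomes.append(Genome(genome_id=genome_id, lineage=lineage, cds_ids=cds_ids))

    descend(0, root_genes, {}, "")

    tree = TaxonomyTree()
    for g in genomes:
        tree.add_genome(g)

    labels_by_genome = [
        {label_of[c] for c in g.cds_ids} for g in genomes
    ]
    universal = set.intersection(*labels_by_genome) if labels_by_genome else set()

    truth = GroundTruth(
        label_of=label_of, genome_of=genome_of, universal_labels=universal
    )
    result = CladeResult(
        genomes=genomes, cds_map=cds_map, taxonomy=tree, truth=truth, spec=spec
    )
    if outdir is not None:
        write_clade(result, outdir)
    return result


def write_clade(result: CladeResult, outdir: str, shuffle_synteny: bool = False,
                seed: int = 0) -> str:
    """Write FASTAs, coordinate tables, the manifest and the truth table.

    With ``shuffle_synteny`` each genome's gene order (hence coordinates)
    is randomly permuted, destroying the constructed collinearity.
    Returns the manifest path.
    """
    from . import io as _io

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest_path = os.path.join(outdir, "manifest.tsv")
    with open(manifest_path, "w") as mf:
        mf.write("\t".join(_io.MANIFEST_COLUMNS) + "\n")
        for g in result.genomes:
            fasta = f"{g.genome_id}.faa"
            cdss = [result.cds_map[c] for c in g.cds_ids]
            if shuffle_synteny:
                order = rng.permutation(len(cdss))
                relocated = []
                pos = 1
                for idx in order:
                    c = cdss[idx]
                    nt_len = 3 * len(c.protein_seq) + 3
                    relocated.append(
                        CDS(c.cds_id, c.genome_id, c.protein_seq, c.contig,
                            pos, pos + nt_len - 1, c.strand, c.product)
                    )
                    pos += nt_len + 100
                cdss = relocated
            _io.write_protein_fasta(cdss, os.path.join(outdir, fasta))
            _io.write_coordinates(cdss, os.path.join(outdir, fasta + ".coords.tsv"))
            row = [g.genome_id] + [g.lineage[r] for r in RANKS] + [fasta]
            mf.write("\t".join(row) + "\n")
    with open(os.path.join(outdir, "truth.tsv"), "w") as tf:
        tf.write("cds_id\tlabel\tgenome_id\tuniversal\n")
        for cid in sorted(result.truth.label_of):
            lab = result.truth.label_of[cid]
            tf.write(
                f"{cid}\t{lab}\t{result.truth.genome_of[cid]}\t"
                f"{int(lab in result.truth.universal_labels)}\n"
            )
    return manifest_path


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------


def _dissimilar_protein(
    rng: np.random.Generator,
    existing: Sequence[str],
    engine: AlignmentEngine,
    lo: int = 50,
    hi: int = 80,
    max_identity: float = 40.0,
    max_tries: int = 50,
) -> str:
    """Rejection-sample a random protein below the identity ceiling
    against every existing sequence."""
    for _ in range(max_tries):
        cand = _random_protein(rng, lo, hi)
        ok = True
        for other in existing:
            hit = engine.local_align(cand, other)
            if hit is not None and hit.identity >= max_identity:
                ok = False
                break
        if ok:
            return cand
    raise RuntimeError("could not sample a mutually dissimilar protein")


def _species_lineage(species: str) -> dict[str, str]:
    lineage = {r: f"{species}_{r}" for r in RANKS}
    lineage["species"] = species
    return lineage


def make_fluidity_fixture(
    sizes: tuple[int, int] = (12, 8),
    shared_count: int = 8,
    seed: int = 0,
) -> tuple[list[Genome], dict[str, CDS]]:
    """Two conspecific genomes with a known shared/unique CDS structure.

    ``shared_count`` CDSs are byte-identical between the genomes; all other
    CDSs are mutually dissimilar random proteins (rejection-sampled below
    40% pairwise identity), so the unique counts are exact by construction.
    """
    if shared_count > min(sizes):
        raise UsageError("shared_count cannot exceed the smaller genome")
    rng = np.random.default_rng(seed)
    engine = AlignmentEngine()
    lineage = _species_lineage("fluidity_sp")
    pool: list[str] = []
    shared = []
    for _ in range(shared_count):
        seq = _dissimilar_protein(rng, pool, engine)
        pool.append(seq)
        shared.append(seq)
    cds_map: dict[str, CDS] = {}
    genomes = []
    for g_idx, size in enumerate(sizes):
        gid = f"flu_g{g_idx + 1}"
        cds_ids = []
        for i in range(size):
            if i < shared_count:
                seq = shared[i]
            else:
                seq = _dissimilar_protein(rng, pool, engine)
                pool.append(seq)
            cid = f"{gid}|c{i + 1:03d}"
            cds_map[cid] = CDS(cds_id=cid, genome_id=gid, protein_seq=seq)
            cds_ids.append(cid)
        genomes.append(Genome(genome_id=gid, lineage=lineage, cds_ids=cds_ids))
    return genomes, cds_map


def occupancy_counts_for_power_law(
    n_genomes: int, kappa: float, alpha: float
) -> list[int]:
    """Per-occupancy accessory-gene counts whose expected first-occurrence
    curve under a random genome order follows ``kappa * N**(-alpha)``.

    For a gene carried by a uniformly random k-subset of G genomes, the
    probability its first carrier sits at position N of a random order is
    ``C(G-N, k-1) / C(G, k)``.  Non-negative least squares against that
    kernel yields occupancy counts (rounded) matching the target curve in
    expectation.
    """
    g = n_genomes
    target = np.array([kappa * n ** (-alpha) for n in range(1, g + 1)])
    kernel = np.zeros((g, g))
    for n in range(1, g + 1):
        for k in range(1, g + 1):
            kernel[n - 1, k - 1] = comb(g - n, k - 1) / comb(g, k)
    counts, _ = nnls(kernel, target)
    return [int(round(c)) for c in counts]


def make_openness_fixture(
    n_genomes: int,
    kappa: float,
    alpha: float,
    seed: int = 0,
    core_size: int = 20,
    length_range: tuple[int, int] = (40, 80),
) -> tuple[list[Genome], dict[str, CDS]]:
    """A species whose expected new-CDS discovery curve follows
    ``kappa * N**(-alpha)`` under random genome orderings.

    Accessory genes are assigned uniform random genome subsets with
    occupancy counts solved from the first-occurrence kernel; a fixed core
    (present everywhere) contributes nothing for N >= 2.  All genes are
    independent random proteins, pairwise unrelated with overwhelming
    probability, so "new" coincides with "first occurrence".
    """
    if n_genomes < 2:
        raise UsageError("openness fixture needs at least two genomes")
    rng = np.random.default_rng(seed)
    counts = occupancy_counts_for_power_law(n_genomes, kappa, alpha)
    gene_carriers: list[tuple[str, str, list[int]]] = []  # (label, seq, genomes)
    for i in range(core_size):
        gene_carriers.append(
            (f"core{i:04d}", _random_protein(rng, *length_range), list(range(n_genomes)))
        )
    acc = 0
    for k, count in enumerate(counts, start=1):
        for _ in range(count):
            carriers = sorted(rng.choice(n_genomes, size=k, replace=False).tolist())
            gene_carriers.append(
                (f"acc{acc:04d}", _random_protein(rng, *length_range), carriers)
            )
            acc += 1
    lineage = _species_lineage("openness_sp")
    cds_map: dict[str, CDS] = {}
    genomes = []
    for g_idx in range(n_genomes):
        gid = f"open_g{g_idx + 1}"
        cds_ids = []
        for label, seq, carriers in gene_carriers:
            if g_idx in carriers:
                cid = f"{gid}|{label}"
                cds_map[cid] = CDS(cds_id=cid, genome_id=gid, protein_seq=seq)
                cds_ids.append(cid)
        genomes.append(Genome(genome_id=gid, lineage=lineage, cds_ids=cds_ids))
    return genomes, cds_map
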