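"""Higher-rank ortholog stage: candidate filtering, hit graph, BBH,
in-paralog augmentation, Markov clustering, explicit/implicit pairs and the
rank climb."""

from __future__ import annotations

import random

import networkx as nx
import numpy as np
import pytest

from oracles import brute_force_bbh

from panorth.level_orthologs import (
    ArtifactStore,
    DependencyError,
    LevelParams,
    bbh_inter_taxon,
    build_hit_graph,
    expand_implicit,
    explicit_pairs,
    filter_candidates,
    in_paralog_augment,
    mcl,
    run_level,
)
from panorth.model import CDS, IntegrityError, OrthologPair, RANKS


PARAMS = LevelParams.defaults_for("genus")


class TestFilterCandidates:
    def _cds(self, seq):
        return CDS("c", "G", seq)

    def test_length_boundary_33(self):
        assert filter_candidates([self._cds("A" * 32)], PARAMS) == []
        kept = filter_candidates([self._cds("A" * 33)], PARAMS)
        assert len(kept) == 1

    def test_trailing_stop_not_counted_in_length(self):
        assert filter_candidates([self._cds("A" * 32 + "*")], PARAMS) == []

    def test_stop_fraction_boundary(self):
        seq = "A" * 97 + "*" * 3  # 3 internal stops out of 100 -> 3% > 2%
        assert filter_candidates([self._cds(seq[:-1] + "A" + "*")], PARAMS) != []
        with_stops = "A" * 48 + "*" + "A" * 48 + "*" + "A" * 3 + "*"  # internal 2/100
        assert filter_candidates([self._cds(with_stops)], PARAMS) != []
        three = "*AA" * 34  # 34 stops in 102 residues
        assert filter_candidates([self._cds(three)], PARAMS) == []

    def test_clean_set_unchanged(self):
        cdss = [self._cds("ACDEFGHIKLMNPQRSTVWY" * 3) for _ in range(4)]
        assert filter_candidates(cdss, PARAMS) == cdss


def _graph(edges, taxa):
    g = nx.Graph()
    for n, t in taxa.items():
        g.add_node(n, taxon=("species", t))
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


class TestBBHInterTaxon:
    def test_single_cross_edge_kept(self):
        g = _graph([("a", "b", 5.0)], {"a": "S1", "b": "S2"})
        assert bbh_inter_taxon(g) == [("a", "b")]

    def test_equal_weight_ties_resolved_deterministically(self):
        g = _graph(
            [("x", "b1", 5.0), ("x", "b2", 5.0), ],
            {"x": "S1", "b1": "S2", "b2": "S2"},
        )
        assert bbh_inter_taxon(g) == [("b1", "x")]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_bipartite_matches_brute_force(self, seed):
        rng = random.Random(seed)
        taxa = {}
        for i in range(8):
            taxa[f"a{i}"] = "S1"
            taxa[f"b{i}"] = "S2"
        edges = []
        for i in range(8):
            for j in range(8):
                if rng.random() < 0.4:
                    edges.append((f"a{i}", f"b{j}", rng.randint(1, 10) * 1.0))
        g = _graph(edges, taxa)
        weights = {}
        for a, b, w in edges:
            weights[(a, b)] = w
            weights[(b, a)] = w
        assert bbh_inter_taxon(g) == brute_force_bbh(
            weights, {n: t for n, t in taxa.items()}
        )


class TestInParalogAugment:
    def test_tight_within_pair_kept(self):
        g = _graph(
            [("a1", "a2", 9.0), ("a1", "b1", 5.0)],
            {"a1": "S1", "a2": "S1", "b1": "S2"},
        )
        bbh = [("a1", "b1")]
        assert in_paralog_augment(g, bbh) == [("a1", "a2")]

    def test_loose_within_pair_dropped(self):
        g = _graph(
            [("a1", "a2", 3.0), ("a1", "b1", 5.0), ("a2", "b1", 4.0)],
            {"a1": "S1", "a2": "S1", "b1": "S2"},
        )
        bbh = [("a1", "b1")]
        assert in_paralog_augment(g, bbh) == []

    def test_isolated_within_duo_dropped(self):
        g = _graph(
            [("a1", "a2", 9.0), ("b1", "b2", 8.0), ("a1", "b1", 5.0)],
            {"a1": "S1", "a2": "S1", "b1": "S2", "b2": "S2"},
        )
        # no BBH pairs at all -> nothing anchored
        assert in_paralog_augment(g, []) == []

    def test_six_node_fixture_matches_hand_derivation(self):
        # S1: a1-a2 tight duo, a3 alone; S2: b1, b2 tight to each other
        g = _graph(
            [
                ("a1", "a2", 10.0),
                ("a1", "b1", 6.0),
                ("a2", "b1", 5.0),
                ("a3", "b2", 7.0),
                ("b1", "b2", 4.0),
            ],
            {"a1": "S1", "a2": "S1", "a3": "S1", "b1": "S2", "b2": "S2"},
        )
        bbh = bbh_inter_taxon(g)
        assert bbh == [("a1", "b1"), ("a3", "b2")]
        # (a1,a2): w=10 >= max_inter(a1)=6 -> kept
        # (b1,b2): w=4 < max_inter(b1)=6 and < max_inter(b2)=7 -> dropped
        assert in_paralog_augment(g, bbh) == [("a1", "a2")]


class TestMCL:
    def test_two_disconnected_triangles_stay_apart(self):
        g = nx.Graph()
        g.add_weighted_edges_from(
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("x", "y", 1), ("y", "z", 1), ("x", "z", 1)]
        )
        assert mcl(g) == [["a", "b", "c"], ["x", "y", "z"]]

    def test_single_node_single_cluster(self):
        g = nx.Graph()
        g.add_node("solo")
        assert mcl(g) == [["solo"]]

    def test_barbell_splits_at_inflation_1_5(self):
        g = nx.Graph()
        for base in ("p", "q"):
            nodes = [f"{base}{i}" for i in range(4)]
            for i, a in enumerate(nodes):
                for b in nodes[i + 1 :]:
                    g.add_edge(a, b, weight=1.0)
        g.add_edge("p3", "q0", weight=0.1)
        clusters = mcl(g, inflation=1.5)
        assert sorted(map(sorted, clusters)) == [
            ["p0", "p1", "p2", "p3"],
            ["q0", "q1", "q2", "q3"],
        ]

    def test_columns_stochastic_after_every_step(self):
        g = nx.Graph()
        rng = random.Random(0)
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.3:
                    g.add_edge(i, j, weight=rng.random() * 5)
        devs = []
        mcl(g, on_step=lambda m: devs.append(np.abs(m.sum(axis=0) - 1.0).max()))
        assert devs and max(devs) < 1e-9

    def test_every_node_in_exactly_one_cluster(self):
        g = nx.Graph()
        rng = random.Random(4)
        for i in range(15):
            g.add_node(i)
            for j in range(i):
                if rng.random() < 0.2:
                    g.add_edge(i, j, weight=1 + rng.random())
        clusters = mcl(g)
        flat = [n for c in clusters for n in c]
        assert sorted(flat) == sorted(g.nodes)


class TestExplicitPairs:
    TAXON = {"a": ("species", "S1"), "b": ("species", "S2"), "c": ("species", "S2")}
    GENOME = {"a": "gA", "b": "gB", "c": "gC"}

    def test_mixed_cluster(self):
        pairs, within = explicit_pairs([["a", "b", "c"]], self.TAXON, self.GENOME, "genus")
        assert {p.key for p in pairs} == {("a", "b"), ("a", "c")}
        assert within == [("b", "c")]

    def test_singleton_cluster_no_pairs(self):
        pairs, within = explicit_pairs([["a"]], self.TAXON, self.GENOME, "genus")
        assert pairs == [] and within == []

    def test_all_distinct_taxa_counting(self):
        taxon = {f"n{i}": ("species", f"S{i}") for i in range(5)}
        genome = {f"n{i}": f"g{i}" for i in range(5)}
        pairs, _ = explicit_pairs([sorted(taxon)], taxon, genome, "genus")
        assert len(pairs) == 10  # 5*4/2


class TestExpandImplicit:
    GENOME = {
        "x": "g1", "x1": "g1b", "x2": "g1c",
        "y": "g2", "y1": "g2b",
    }

    def test_trivial_singletons_expand_to_nothing(self):
        expl = [OrthologPair.make("x", "y", "genus", "explicit")]
        out = expand_implicit(expl, {"x": ["x"], "y": ["y"]}, self.GENOME)
        assert out == []

    def test_three_by_two_members_give_five(self):
        expl = [OrthologPair.make("x", "y", "genus", "explicit")]
        out = expand_implicit(
            expl, {"x": ["x", "x1", "x2"], "y": ["y", "y1"]}, self.GENOME
        )
        assert len(out) == 5
        assert all(p.provenance == "implicit" for p in out)

    def test_shared_members_deduplicated_against_product_oracle(self):
        members = {"x": ["x", "x1"], "y": ["y", "y1"], "x1": ["x", "x1"]}
        expl = [
            OrthologPair.make("x", "y", "genus", "explicit"),
            OrthologPair.make("x1", "y", "genus", "explicit"),
        ]
        out = expand_implicit(expl, members, self.GENOME)
        # oracle: full cross product minus explicit keys, same-genome, dups
        explicit_keys = {p.key for p in expl}
        oracle = set()
        for p in expl:
            for a in members[p.cds_a]:
                for b in members[p.cds_b]:
                    if self.GENOME[a] == self.GENOME[b]:
                        continue
                    k = (a, b) if a < b else (b, a)
                    if k not in explicit_keys:
                        oracle.add(k)
        assert {p.key for p in out} == oracle
        assert len(out) == len({p.key for p in out})

    def test_unknown_entry_rejected(self):
        expl = [OrthologPair.make("x", "y", "genus", "explicit")]
        with pytest.raises(IntegrityError):
            expand_implicit(expl, {"x": ["x"]}, self.GENOME)


class TestHitGraphAndRunLevel:
    def test_hit_graph_thresholds(self, engine, small_clade_run):
        clade, result, _ = small_clade_run
        # two species pan-genomes under one genus
        genus = clade.taxonomy.taxa_at_rank("genus")[0]
        children = clade.taxonomy.children_of(genus)
        admissible = {
            c: filter_candidates(
                [clade.cds_map[e] for e in result.store.pangenomes[c].entries], PARAMS
            )
            for c in children
        }
        graph = build_hit_graph(admissible, engine, PARAMS)
        for _x, _y, data in graph.edges(data=True):
            assert 0 < data["weight"] <= 300

    def test_run_level_requires_child_artifacts(self, small_clade, engine):
        store = ArtifactStore()
        with pytest.raises(DependencyError):
            run_level("genus", small_clade.taxonomy, store, small_clade.cds_map, engine)

    def test_single_child_taxon_passes_pangenome_through(self, small_clade_run):
        clade, result, _ = small_clade_run
        family = clade.taxonomy.taxa_at_rank("family")[0]
        order = clade.taxonomy.taxa_at_rank("order")[0]
        fam_pg = result.store.pangenomes[family]
        ord_pg = result.store.pangenomes[order]
        assert sorted(ord_pg.entries) == sorted(fam_pg.entries)

    def test_pair_level_equals_lca_rank(self, small_clade_run):
        clade, result, _ = small_clade_run
        lineages = {g.genome_id: g.lineage for g in clade.genomes}
        genome_of = clade.truth.genome_of
        for p in result.store.pairs:
            la = lineages[genome_of[p.cds_a]]
            lb = lineages[genome_of[p.cds_b]]
            lca = next(r for r in RANKS if la[r] == lb[r])
            assert p.level == lca

    def test_fewer_comparisons_than_full_all_vs_all(self, small_clade_run):
        _clade, result, _ = small_clade_run
        for report in result.store.reports:
            assert report.n_comparisons < report.n_full_cds_comparisons

    def test_explicit_and_implicit_sets_disjoint(self, small_clade_run):
        _clade, result, _ = small_clade_run
        keys = [p.key for p in result.store.pairs]
        assert len(keys) == len(set(keys))
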