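"""Alignment engine: DP-oracle score equality, identity/coverage
definitions, e-value formula, all-vs-all equivalence, synteny chaining and
six-frame translation."""

from __future__ import annotations

import math
import random

import pytest

from oracles import dp_local_score

from panorth.align import (
    AlignmentEngine,
    InputError,
    ScoringScheme,
    estimate_evalue,
    six_frame_translate,
    syntenic_blocks,
)
from panorth.model import CDS, SimilarityHit, UsageError

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rand(rng, n):
    return "".join(rng.choice(AA20) for _ in range(n))


class TestLocalAlign:
    def test_self_alignment_is_perfect(self, engine):
        rng = random.Random(0)
        for n in (10, 33, 80):
            s = _rand(rng, n)
            hit = engine.local_align(s, s)
            assert hit.identity == 100.0
            assert hit.coverage == 100.0

    def test_three_mismatches_in_thirty(self, engine):
        """A 30-mer pair differing at 3 positions aligns end to end:
        identity 90, coverage 100."""
        a = "MKVLITAGPTREPLDPVRYISNHSSGKMGF"
        b = a[:5] + "W" + a[6:14] + "W" + a[15:22] + "C" + a[23:]
        assert len(b) == 30 and sum(x != y for x, y in zip(a, b)) == 3
        hit = engine.local_align(a, b)
        assert hit.identity == pytest.approx(90.0)
        assert hit.coverage == pytest.approx(100.0)

    def test_score_matches_dp_oracle(self, engine):
        """Engine score equals the textbook affine-gap DP on 200 random
        pairs of length <= 50."""
        rng = random.Random(42)
        for _ in range(200):
            a = _rand(rng, rng.randint(5, 50))
            b = _rand(rng, rng.randint(5, 50))
            oracle = dp_local_score(a, b)
            hit = engine.local_align(a, b)
            got = 0.0 if hit is None else hit.score
            if oracle >= engine.scheme.score_floor:
                assert got == pytest.approx(oracle)
            else:
                assert hit is None

    def test_symmetry_under_swap(self, engine):
        rng = random.Random(1)
        for _ in range(30):
            a, b = _rand(rng, rng.randint(20, 60)), _rand(rng, rng.randint(20, 60))
            h1 = engine.local_align(a, b)
            h2 = engine.local_align(b, a)
            if h1 is None:
                assert h2 is None
                continue
            assert h1.score == h2.score
            assert h1.identity == h2.identity
            assert h1.coverage == h2.coverage

    def test_unrelated_sequences_stay_below_70_70(self, engine):
        """Independent random 100-mers essentially never clear 70/70."""
        rng = random.Random(123)
        for _ in range(50):
            hit = engine.local_align(_rand(rng, 100), _rand(rng, 100))
            if hit is not None:
                assert not (hit.identity >= 70 and hit.coverage >= 70)

    def test_illegal_residue_rejected(self, engine):
        with pytest.raises(InputError):
            engine.local_align("MKV1", "MKVL")

    def test_trailing_stop_stripped(self, engine):
        hit = engine.local_align("MKVLITAGPTREPLDPVRYISNHSSGKMGF*",
                                 "MKVLITAGPTREPLDPVRYISNHSSGKMGF")
        assert hit.identity == 100.0 and hit.coverage == 100.0


class TestEvalue:
    def test_monotone_decreasing_in_score(self):
        assert estimate_evalue(100, 200, 200) < estimate_evalue(50, 200, 200)

    def test_linear_in_search_space(self):
        e1 = estimate_evalue(80, 100, 100, search_space=1e4)
        e2 = estimate_evalue(80, 100, 100, search_space=2e4)
        assert e2 == pytest.approx(2 * e1)

    def test_closed_form(self):
        scheme = ScoringScheme()
        for score, m, n in [(40, 100, 200), (75, 333, 50), (120, 1000, 1000)]:
            expected = scheme.ka_k * m * n * math.exp(-scheme.ka_lambda * score)
            assert estimate_evalue(score, m, n) == pytest.approx(expected, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(UsageError):
            estimate_evalue(10, 0, 5)
        with pytest.raises(UsageError):
            estimate_evalue(float("nan"), 5, 5)


class TestAllVsAll:
    def test_matches_nested_loop_oracle(self, engine):
        rng = random.Random(7)
        set_a = [CDS(f"a{i}", "GA", _rand(rng, rng.randint(30, 60))) for i in range(20)]
        set_b = [CDS(f"b{i}", "GB", _rand(rng, rng.randint(30, 60))) for i in range(20)]
        # two diverged copies so at least some hits pass
        set_b[3] = CDS("b3", "GB", set_a[5].protein_seq[:-2] + "AA")
        hits = engine.all_vs_all(set_a, set_b, min_identity=70, min_coverage=70)
        expected = {}
        for ca in set_a:
            for cb in set_b:
                h = engine.local_align(ca.protein_seq, cb.protein_seq, ca.cds_id, cb.cds_id)
                if h and h.identity >= 70 and h.coverage >= 70:
                    expected[(ca.cds_id, cb.cds_id)] = h.score
        assert {(h.query_id, h.subject_id): h.score for h in hits} == expected

    def test_mirror_symmetry(self, engine):
        rng = random.Random(9)
        set_a = [CDS(f"a{i}", "GA", _rand(rng, 40)) for i in range(5)]
        set_b = [CDS(f"b{i}", "GB", set_a[i % 5].protein_seq) for i in range(5)]
        ab = engine.all_vs_all(set_a, set_b)
        ba = engine.all_vs_all(set_b, set_a)
        assert {(h.query_id, h.subject_id, h.score) for h in ab} == {
            (h.subject_id, h.query_id, h.score) for h in ba
        }

    def test_self_mode_excludes_self_hits(self, engine):
        rng = random.Random(2)
        cdss = [CDS(f"c{i}", "G", _rand(rng, 50)) for i in range(4)]
        cdss.append(CDS("dup", "G", cdss[0].protein_seq))
        hits = engine.all_vs_all(cdss, cdss)
        assert all(h.query_id != h.subject_id for h in hits)
        assert all(h.query_id < h.subject_id for h in hits)
        assert ("c0", "dup") in {(h.query_id, h.subject_id) for h in hits}

    def test_empty_collection_rejected(self, engine):
        with pytest.raises(UsageError):
            engine.all_vs_all([], [])


def _cds(cid, genome, contig, start, end, strand="+"):
    return CDS(cid, genome, "M" * 20, contig=contig, start=start, end=end, strand=strand)


def _hit(q, s):
    return SimilarityHit(q, s, 90.0, 100.0, 80.0, 1e-20, 20)


class TestSyntenicBlocks:
    def _collinear_maps(self, n):
        cds_map = {}
        hits = []
        for i in range(n):
            a = _cds(f"a{i}", "GA", "ca", 1000 * i + 1, 1000 * i + 500)
            b = _cds(f"b{i}", "GB", "cb", 1000 * i + 1, 1000 * i + 500)
            cds_map[a.cds_id], cds_map[b.cds_id] = a, b
            hits.append(_hit(a.cds_id, b.cds_id))
        return cds_map, hits

    def test_identical_gene_order_single_block(self):
        cds_map, hits = self._collinear_maps(8)
        blocks = syntenic_blocks(hits, cds_map)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 8
        assert blocks[0].orientation == "same"

    def test_inverted_segment_forms_own_block(self):
        cds_map, hits = self._collinear_maps(9)
        # invert the middle 3 genes on genome B: reverse order + strand flip
        for k, i in enumerate((3, 4, 5)):
            j = 5 - k  # 3->5, 4->4, 5->3
            b = _cds(f"b{i}", "GB", "cb", 1000 * j + 1, 1000 * j + 500, strand="-")
            cds_map[f"b{i}"] = b
        blocks = syntenic_blocks(hits, cds_map)
        inverted = [bl for bl in blocks if bl.orientation == "inverted"]
        assert len(inverted) == 1
        assert sorted(a for a, _ in inverted[0].anchors) == ["a3", "a4", "a5"]
        assert all(len(bl.anchors) > 0 for bl in blocks)

    def test_no_anchors_empty(self):
        assert syntenic_blocks([], {}) == []

    def test_each_anchor_in_exactly_one_block(self):
        cds_map, hits = self._collinear_maps(10)
        # a couple of off-diagonal (co-ortholog) anchors
        extra = _cds("b_extra", "GB", "cb", 50_000, 50_500)
        cds_map["b_extra"] = extra
        hits.append(_hit("a2", "b_extra"))
        blocks = syntenic_blocks(hits, cds_map)
        seen = [a for bl in blocks for a in bl.anchors]
        assert len(seen) == len(set(seen)) == len(hits)

    def test_fallback_without_coordinates(self):
        cds_map = {
            "a0": CDS("a0", "GA", "MKLMKL"),
            "b0": CDS("b0", "GB", "MKLMKL"),
        }
        blocks = syntenic_blocks([_hit("a0", "b0")], cds_map)
        assert len(blocks) == 1 and blocks[0].length == 1


class TestSixFrame:
    def test_standard_code_frame1(self):
        assert six_frame_translate("ATGAAATAG")[0] == "MK*"

    def test_reverse_frames_equal_revcomp_translation(self):
        from Bio.Seq import Seq

        seq = "ATGGCCATTGTAATGGGCCGCTGAAAGGGTGCCCGATAG"
        frames = six_frame_translate(seq)
        rc = str(Seq(seq).reverse_complement())
        for f in range(3):
            sub = rc[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            assert frames[3 + f] == str(Seq(sub).translate())

    def test_frame_lengths(self):
        seq = "ACGTACGTACG"  # length 11
        frames = six_frame_translate(seq)
        for f in range(3):
            expected = (11 - f) // 3
            assert len(frames[f]) == expected
            assert len(frames[3 + f]) == expected

    def test_ambiguous_codon_is_x(self):
        assert six_frame_translate("ATGNNN")[0] == "MX"

    def test_illegal_base_rejected(self):
        with pytest.raises(InputError):
            six_frame_translate("ACGU")
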