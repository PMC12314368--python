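import random

import pytest

from nsrscan.collinearity import (
    AnchorPair,
    CollinearBlock,
    CollinearParams,
    block_evalue,
    build_anchors,
    chain_anchors,
    collapse_tandem_anchors,
    homologous_gene_flags,
)
from nsrscan.kaks import KaKsResult
from nsrscan.model import HitRecord

from _oracles import best_chain_score_oracle, longest_monotone_chain
from conftest import make_gene


def hit(q, s, evalue=1e-30, bits=200.0):
    return HitRecord(q, s, 95.0, 100, 5, 0, 1, 100, 1, 100, evalue, bits)


def diag_anchors(n, offset=0):
    return [AnchorPair(i + offset, i + offset, f"a{i+offset}", f"b{i+offset}", 1e-30) for i in range(n)]


class TestBuildAnchors:
    def setup_method(self):
        self.genes_a = [make_gene(f"a{i}", i * 100, i * 100 + 50) for i in range(10)]
        self.genes_b = [make_gene(f"b{i}", i * 100, i * 100 + 50, scaffold="scf1") for i in range(10)]

    def test_evalue_cut(self):
        anchors = build_anchors([hit("a0", "b0", evalue=1e-3)], self.genes_a, self.genes_b)
        assert anchors == []

    def test_diagonal(self):
        hits = [hit(f"a{i}", f"b{i}") for i in range(10)]
        anchors = build_anchors(hits, self.genes_a, self.genes_b)
        assert [(a.index_a, a.index_b) for a in anchors] == [(i, i) for i in range(10)]

    def test_duplicate_pair_keeps_best(self):
        anchors = build_anchors(
            [hit("a1", "b1", evalue=1e-10), hit("a1", "b1", evalue=1e-40)],
            self.genes_a, self.genes_b,
        )
        assert len(anchors) == 1 and anchors[0].hit_evalue == 1e-40

    def test_unknown_gene(self):
        with pytest.raises(KeyError, match="zz"):
            build_anchors([hit("zz", "b0")], self.genes_a, self.genes_b)


class TestBlockEvalue:
    def test_perfect_diagonal_passes_cut(self):
        assert block_evalue(20, 20, 20, 20, 20, 20) < 1e-5

    def test_two_anchor_block_fails_cut(self):
        assert block_evalue(2, 50, 50, 500, 100, 100) >= 1e-5

    def test_monotone_decreasing_in_anchor_count(self):
        prev = 2.0
        for m in range(1, 21):
            e = block_evalue(m, 40, 40, 200, 100, 100)
            assert e <= prev
            prev = e

    def test_zero_size_rectangle(self):
        with pytest.raises(ValueError):
            block_evalue(5, 0, 10, 10, 100, 100)

    def test_monte_carlo_oracle(self):
        # 20 anchors uniform in a 20x20 grid essentially never contain a
        # 20-long monotone chain; consistent with e-value < 1e-5
        rnd = random.Random(0)
        n_hits = 0
        for _ in range(10_000):
            pts = {(rnd.randrange(20), rnd.randrange(20)) for _ in range(20)}
            if longest_monotone_chain(list(pts)) >= 20:
                n_hits += 1
        assert n_hits == 0
        assert block_evalue(20, 20, 20, 20, 20, 20) < 1e-5

    def test_monte_carlo_weak_block(self):
        # a 2-anchor "block" arises constantly in a dense random field
        rnd = random.Random(1)
        n_hits = 0
        for _ in range(300):
            pts = [(rnd.randrange(100), rnd.randrange(100)) for _ in range(120)]
            if longest_monotone_chain(pts) >= 2:
                n_hits += 1
        assert n_hits / 300 > 0.99
        assert block_evalue(2, 50, 50, 500, 100, 100) >= 1e-5


class TestChainAnchors:
    def test_perfect_diagonal_block(self):
        (block,) = chain_anchors(diag_anchors(20))
        assert len(block.anchors) == 20
        assert block.orientation == "parallel"
        assert block.score == pytest.approx(20 * 50.0)

    def test_match_size_floor(self):
        assert chain_anchors(diag_anchors(9)) == []

    def test_antiparallel(self):
        anchors = [AnchorPair(i, 19 - i, f"a{i}", f"b{19-i}", 1e-30) for i in range(20)]
        (block,) = chain_anchors(anchors)
        assert block.orientation == "antiparallel"
        assert len(block.anchors) == 20

    def test_hidden_run_recovered(self):
        rnd = random.Random(42)
        noise = []
        used = set()
        while len(noise) < 30:
            ia, ib = rnd.randrange(40), rnd.randrange(40)
            # keep noise off the diagonal band so no random monotone run >= 10
            if abs(ia - ib) < 5 or (ia, ib) in used:
                continue
            used.add((ia, ib))
            noise.append(AnchorPair(ia, ib, f"na{ia}", f"nb{ib}", 1e-10))
        signal = [AnchorPair(i, i, f"sa{i}", f"sb{i}", 1e-30) for i in range(12)]
        assert longest_monotone_chain([(a.index_a, a.index_b) for a in noise]) < 10
        blocks = chain_anchors(noise + signal, CollinearParams(), 40, 40)
        assert len(blocks) == 1
        got = {(a.index_a, a.index_b) for a in blocks[0].anchors}
        assert {(i, i) for i in range(12)} <= got

    def test_k_disjoint_diagonals(self):
        anchors = []
        for k in range(3):
            anchors += diag_anchors(12, offset=k * 40)
        blocks = chain_anchors(anchors, CollinearParams(), 120, 120)
        assert len(blocks) == 3
        covered = {(a.index_a, a.index_b) for b in blocks for a in b.anchors}
        assert covered == {(a.index_a, a.index_b) for a in anchors}

    def test_input_order_invariance(self):
        anchors = diag_anchors(15) + [AnchorPair(30, 5, "x", "y", 1e-8)]
        b1 = chain_anchors(list(anchors), CollinearParams(), 40, 40)
        rnd = random.Random(3)
        shuffled = list(anchors)
        rnd.shuffle(shuffled)
        b2 = chain_anchors(shuffled, CollinearParams(), 40, 40)
        assert [tuple(a.gene_a for a in b.anchors) for b in b1] == [
            tuple(a.gene_a for a in b.anchors) for b in b2
        ]

    def test_blocks_satisfy_invariants(self):
        rnd = random.Random(9)
        anchors = [
            AnchorPair(i, i + rnd.randrange(-2, 3), f"a{i}", f"b{i}", 1e-30)
            for i in range(0, 60, 2)
        ]
        params = CollinearParams()
        for block in chain_anchors(anchors, params, 70, 70):
            sign = 1 if block.orientation == "parallel" else -1
            for prev, cur in zip(block.anchors, block.anchors[1:]):
                da = cur.index_a - prev.index_a
                db = sign * (cur.index_b - prev.index_b)
                assert 0 < da <= params.max_gaps
                assert 0 < db <= params.max_gaps
            assert len(block.anchors) >= params.match_size
            assert block.e_value <= params.e_value_cut

    def test_dp_matches_exhaustive_oracle(self):
        params = CollinearParams(match_size=2, e_value_cut=1.0)
        for seed in range(20):
            rnd = random.Random(seed)
            pts = {(rnd.randrange(15), rnd.randrange(15)) for _ in range(25)}
            anchors = [AnchorPair(a, b, f"a{a}_{b}", f"b{a}_{b}", 1e-30) for a, b in sorted(pts)]
            blocks = chain_anchors(anchors, params, 15, 15, collapse_tandem=False)
            top = max((b.score for b in blocks), default=0.0)
            oracle = best_chain_score_oracle(
                anchors, params.match_score, params.gap_penalty, params.max_gaps
            )
            assert top == pytest.approx(oracle), seed

    def test_tandem_collapse(self):
        # three rank-consecutive genes on A all hitting b5 collapse to one anchor
        anchors = [
            AnchorPair(4, 5, "a4", "b5", 1e-10),
            AnchorPair(5, 5, "a5", "b5", 1e-40),
            AnchorPair(6, 5, "a6", "b5", 1e-20),
        ]
        collapsed = collapse_tandem_anchors(anchors)
        assert len(collapsed) == 1 and collapsed[0].gene_a == "a5"


class TestHomologFlags:
    def _block(self):
        anchors = tuple(AnchorPair(i, i, f"a{i}", f"b{i}", 1e-30) for i in range(10))
        return CollinearBlock(anchors, "parallel", 500.0, 1e-12, "sA", "sB")

    def _kaks(self, ks):
        return KaKsResult(10, 20, 1, 1, 0.1, 0.05, 0.01, ks, None)

    def test_low_ks_flags_both_genes(self):
        block = self._block()
        results = {(f"a{i}", f"b{i}"): self._kaks(0.01) for i in range(10)}
        flags = homologous_gene_flags([block], results)
        assert flags["a0"] and flags["b0"]

    def test_gene_outside_blocks_absent(self):
        block = self._block()
        results = {(f"a{i}", f"b{i}"): self._kaks(0.01) for i in range(10)}
        flags = homologous_gene_flags([block], results)
        assert "a99" not in flags

    def test_saturated_pair_not_homologous(self):
        block = self._block()
        results = {(f"a{i}", f"b{i}"): self._kaks(None) for i in range(10)}
        flags = homologous_gene_flags([block], results)
        assert not any(flags.values())

    def test_missing_kaks_raises(self):
        block = self._block()
        with pytest.raises(KeyError, match="missing Ka/Ks"):
            homologous_gene_flags([block], {})
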