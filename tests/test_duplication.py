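import random

import networkx as nx
import pytest

from nsrscan.duplication import (
    OrthoGroup,
    call_sstdg,
    cluster_orthogroups_fallback,
    find_tdg_pairs,
    read_orthogroups,
    sstdg_nsr_overlap,
    write_orthogroups,
)
from nsrscan.model import HitRecord
from nsrscan.nsr_caller import NSRInterval

from _oracles import tdg_pairs_bruteforce
from conftest import make_gene


def hit(q, s, bits=200.0, evalue=1e-30):
    return HitRecord(q, s, 95.0, 100, 5, 0, 1, 100, 1, 100, evalue, bits)


class TestOrthogroupIO:
    def test_read_orthomcl_style(self, tmp_path):
        p = tmp_path / "groups.txt"
        p.write_text("OG1: spA|g1 spB|g2\nOG2: spA|g3\n")
        groups = read_orthogroups(p)
        assert groups[0].members == ("g1", "g2")
        assert groups[1].group_id == "OG2"

    def test_roundtrip(self, tmp_path):
        groups = [OrthoGroup("OG1", ("g1", "g2"))]
        p = tmp_path / "rt.txt"
        write_orthogroups(groups, {"g1": "spA", "g2": "spB"}, p)
        back = read_orthogroups(p)
        assert back[0].members == ("g1", "g2")


class TestFallbackClustering:
    def test_rbh_square(self):
        genome_of = {"a1": "gA", "a2": "gA", "b1": "gB", "b2": "gB"}
        hits = [
            hit("a1", "b1"), hit("b1", "a1"),
            hit("a2", "b2"), hit("b2", "a2"),
            hit("a1", "a2"), hit("a2", "a1"),  # within-genome edge joins all
        ]
        groups = cluster_orthogroups_fallback(hits, genome_of)
        assert len(groups) == 1 and set(groups[0].members) == set(genome_of)

    def test_singleton(self):
        groups = cluster_orthogroups_fallback([], {"solo": "gA"})
        assert len(groups) == 1 and groups[0].members == ("solo",)

    def test_non_reciprocal_not_joined(self):
        genome_of = {"a1": "gA", "b1": "gB", "b2": "gB"}
        # a1's best in gB is b1, but b1's best in gA points elsewhere-less: make
        # b1 -> a1 absent entirely
        hits = [hit("a1", "b1")]
        groups = cluster_orthogroups_fallback(hits, genome_of)
        assert len(groups) == 3

    def test_random_graph_matches_components_oracle(self):
        rnd = random.Random(17)
        genes = [f"g{i}" for i in range(20)]
        genome_of = {g: f"G{i % 3}" for i, g in enumerate(genes)}
        hits = []
        g = nx.Graph()
        g.add_nodes_from(genes)
        # within-genome random edges (always honoured by the fallback)
        for _ in range(15):
            a, b = rnd.sample(genes, 2)
            if genome_of[a] == genome_of[b]:
                hits.append(hit(a, b))
                g.add_edge(a, b)
        # cross-genome reciprocal best pairs: use distinct bit scores so the
        # best hit is unambiguous and reciprocal by construction
        for _ in range(8):
            a, b = rnd.sample(genes, 2)
            if genome_of[a] != genome_of[b] and not any(
                genome_of[x] == genome_of[b] and g.has_edge(a, x) for x in genes
            ):
                hits.append(hit(a, b, bits=900))
                hits.append(hit(b, a, bits=900))
                g.add_edge(a, b)
        groups = cluster_orthogroups_fallback(hits, genome_of)
        got = {frozenset(grp.members) for grp in groups}
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert got == expected


class TestTdgPairs:
    def test_adjacent(self):
        genes = [make_gene("A1", 0, 100), make_gene("A2", 200, 300)]
        pairs = find_tdg_pairs(genes, {"A1": "G", "A2": "G"})
        assert len(pairs) == 1 and pairs[0].intervening_unrelated == 0

    def test_one_unrelated_between(self):
        genes = [make_gene("A1", 0, 100), make_gene("X", 200, 300), make_gene("A2", 400, 500)]
        pairs = find_tdg_pairs(genes, {"A1": "G", "A2": "G", "X": "H"})
        assert len(pairs) == 1 and pairs[0].intervening_unrelated == 1

    def test_distance_three_no_pair(self):
        genes = [
            make_gene("A1", 0, 100), make_gene("X", 200, 300),
            make_gene("Y", 400, 500), make_gene("A2", 600, 700),
        ]
        pairs = find_tdg_pairs(genes, {"A1": "G", "A2": "G", "X": "H", "Y": "I"})
        assert pairs == []

    def test_related_intervening_means_two_adjacent_pairs(self):
        genes = [make_gene("A1", 0, 100), make_gene("A2", 200, 300), make_gene("A3", 400, 500)]
        group_of = {g: "G" for g in ("A1", "A2", "A3")}
        pairs = find_tdg_pairs(genes, group_of)
        keys = {(p.gene_a, p.gene_b) for p in pairs}
        assert ("A1", "A2") in keys and ("A2", "A3") in keys
        assert ("A1", "A3") not in keys  # intervening A2 is related

    def test_bruteforce_equivalence(self, rng):
        for trial in range(10):
            genes = [
                make_gene(f"g{trial}_{i}", i * 100, i * 100 + 60,
                          scaffold=f"s{int(rng.integers(0, 3))}")
                for i in range(200)
            ]
            group_of = {g.gene_id: f"G{int(rng.integers(0, 40))}" for g in genes}
            got = {(p.gene_a, p.gene_b) for p in find_tdg_pairs(genes, group_of)}
            assert got == tdg_pairs_bruteforce(genes, group_of)


def _tags(mapping):
    return mapping


class TestSstdg:
    def _setup(self, counts, tandem=True):
        """counts: {(species, hap): n_copies}; build genes + group + pairs."""
        members, tags, genes = [], {}, []
        tdg = []
        for (sp, hp), n in counts.items():
            ids = [f"{sp}_{hp}_c{i}" for i in range(n)]
            members += ids
            for i, gid in enumerate(ids):
                tags[gid] = (sp, hp)
                genes.append(make_gene(gid, i * 200, i * 200 + 100, scaffold=f"{sp}_{hp}"))
            if n == 2 and tandem:
                from nsrscan.duplication import TDGPair

                tdg.append(TDGPair(ids[0], ids[1], f"{sp}_{hp}", 0))
        group = OrthoGroup("OG1", tuple(members))
        return [group], tdg, tags, genes

    def test_canonical_sstdg(self):
        groups, tdg, tags, _ = self._setup(
            {("X", "h1"): 1, ("X", "h2"): 1, ("Y", "h1"): 2, ("Y", "h2"): 2}
        )
        (call,) = call_sstdg(groups, tdg, tags, ("X", "Y"))
        assert call.expanded_species == "Y"

    def test_unequal_haplotype_copy_number_rejected(self):
        groups, tdg, tags, _ = self._setup(
            {("X", "h1"): 1, ("X", "h2"): 1, ("Y", "h1"): 2, ("Y", "h2"): 1}
        )
        assert call_sstdg(groups, tdg, tags, ("X", "Y")) == []

    def test_no_single_copy_species_rejected(self):
        groups, tdg, tags, _ = self._setup(
            {("X", "h1"): 2, ("X", "h2"): 2, ("Y", "h1"): 2, ("Y", "h2"): 2}
        )
        assert call_sstdg(groups, tdg, tags, ("X", "Y")) == []

    def test_non_tandem_rejected(self):
        groups, tdg, tags, _ = self._setup(
            {("X", "h1"): 1, ("X", "h2"): 1, ("Y", "h1"): 2, ("Y", "h2"): 2},
            tandem=False,
        )
        assert call_sstdg(groups, [], tags, ("X", "Y")) == []

    def test_species_label_symmetry(self):
        groups, tdg, tags, _ = self._setup(
            {("X", "h1"): 1, ("X", "h2"): 1, ("Y", "h1"): 2, ("Y", "h2"): 2}
        )
        c1 = call_sstdg(groups, tdg, tags, ("X", "Y"))
        c2 = call_sstdg(groups, tdg, tags, ("Y", "X"))
        assert c1[0].expanded_species == c2[0].expanded_species == "Y"

    def test_calls_reference_existing_tdg_pairs(self):
        groups, tdg, tags, _ = self._setup(
            {("X", "h1"): 1, ("X", "h2"): 1, ("Y", "h1"): 2, ("Y", "h2"): 2}
        )
        calls = call_sstdg(groups, tdg, tags, ("X", "Y"))
        tdg_keys = {p.key() for p in tdg}
        assert all(c.pair.key() in tdg_keys for c in calls)


class TestOverlapFractions:
    def _call(self, i, scaffold, start):
        from nsrscan.duplication import SSTDGCall, TDGPair

        pair = TDGPair(f"p{i}a", f"p{i}b", scaffold, 0)
        return SSTDGCall(f"OG{i}", "Y", (), pair), {
            f"p{i}a": make_gene(f"p{i}a", start, start + 100, scaffold=scaffold),
            f"p{i}b": make_gene(f"p{i}b", start + 200, start + 300, scaffold=scaffold),
        }

    def _fraction(self, n_in, n_total):
        calls, coords = [], {}
        ivs = [NSRInterval("s1", 0, 10_000)]
        for i in range(n_total):
            start = 1000 if i < n_in else 50_000
            c, g = self._call(i, "s1", start)
            calls.append(c)
            coords.update(g)
        return sstdg_nsr_overlap(calls, ivs, coords)

    def test_7_of_56(self):
        assert self._fraction(7, 56) == (7, 56, 12.5)

    def test_20_of_119(self):
        assert self._fraction(20, 119) == (20, 119, 16.8)

    def test_none_inside(self):
        assert self._fraction(0, 10) == (0, 10, 0.0)
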