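import itertools
from pathlib import Path

import numpy as np
import pytest

from nsrscan import io_formats
from nsrscan.kaks import CODON_TABLE, STOP_CODONS
from nsrscan.pipeline import PipelineConfig, run_pipeline
from nsrscan.simulate import (
    SimConfig,
    _UidSource,
    _candidate_te_pairs,
    apply_unequal_crossover,
    emit_dataset,
    simulate,
)


def small_config(**kw):
    defaults = dict(seed=3, genes_per_scaffold=60, te_insertions=25,
                    hotspot_fraction=0.2, n_hotspots=1, n_nahr_events=0)
    defaults.update(kw)
    return SimConfig(**defaults)


def all_genes(result):
    for hap in result.haplotypes:
        for scf in hap.scaffolds:
            for seg in scf.segments:
                if seg.gene is not None:
                    yield scf, seg


class TestAncestorAndGenes:
    def test_gene_count(self):
        res = simulate(small_config())
        per_hap = [
            sum(1 for s in hap.scaffolds for seg in s.segments if seg.kind == "gene")
            for hap in res.haplotypes
        ]
        assert per_hap == [60, 60]

    def test_genes_do_not_overlap(self):
        res = simulate(small_config())
        for hap in res.haplotypes:
            for scf in hap.scaffolds:
                coords = [
                    (s, e) for seg, (s, e) in zip(scf.segments, scf.coordinates())
                    if seg.kind == "gene"
                ]
                for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
                    assert e1 <= s2

    def test_cds_framed_and_stop_free(self):
        res = simulate(small_config(n_nahr_events=5))
        for _, seg in all_genes(res):
            cds = seg.gene.cds
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG") and cds[-3:] in STOP_CODONS
            internal = [cds[i : i + 3] for i in range(3, len(cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_config(n_nahr_events=4)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        emit_dataset(simulate(cfg), d1)
        emit_dataset(simulate(cfg), d2)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p1.read_bytes() == p2.read_bytes(), p1.name


class TestTransposons:
    def test_rate_zero_no_tes(self):
        res = simulate(small_config(te_insertions=0))
        for hap in res.haplotypes:
            assert not any(
                seg.kind == "te" for s in hap.scaffolds for seg in s.segments
            )

    def test_te_never_overlaps_cds(self):
        res = simulate(small_config(te_insertions=60))
        for hap in res.haplotypes:
            for scf in hap.scaffolds:
                spans = list(zip(scf.segments, scf.coordinates()))
                genes = [(s, e) for seg, (s, e) in spans if seg.kind == "gene"]
                tes = [(s, e) for seg, (s, e) in spans if seg.kind == "te"]
                for ts, te_ in tes:
                    for gs, ge in genes:
                        assert te_ <= gs or ts >= ge

    def test_hotspot_bias(self):
        cfg = small_config(genes_per_scaffold=200, te_insertions=300,
                           hotspot_fraction=0.2, te_hotspot_bias=25.0)
        res = simulate(cfg)
        in_hot = total = 0
        for hap in res.haplotypes:
            for scf in hap.scaffolds:
                for seg in scf.segments:
                    if seg.kind == "te":
                        total += 1
                        in_hot += seg.hotspot >= 0
        # ~20% of length holds the hotspot; with 25x bias well over half land inside
        assert total > 0 and in_hot / total > 0.5


class TestUnequalCrossover:
    def _sim_with_tes(self):
        res = simulate(small_config(te_insertions=80, genes_per_scaffold=100))
        return res

    def test_single_event_conserves_gene_count(self):
        res = self._sim_with_tes()
        hap1, hap2 = res.haplotypes
        scf1, scf2 = hap1.scaffolds[0], hap2.scaffolds[0]
        pairs = _candidate_te_pairs(scf1, max_genes=3)
        assert pairs, "no eligible TE pairs in test fixture"
        i, j, _ = pairs[0]
        before = sum(1 for h in (hap1, hap2) for s in h.scaffolds
                     for seg in s.segments if seg.kind == "gene")
        gained, lost, interval = apply_unequal_crossover(scf1, scf2, i, j, _UidSource())
        after = sum(1 for h in (hap1, hap2) for s in h.scaffolds
                    for seg in s.segments if seg.kind == "gene")
        assert len(gained) >= 1 and len(lost) >= 1
        assert after == before + len(gained) - len(lost)
        assert interval[0] < interval[1]

    def test_duplicated_copy_is_tandem(self):
        res = self._sim_with_tes()
        hap1, hap2 = res.haplotypes
        scf1 = hap1.scaffolds[0]
        pairs = [p for p in _candidate_te_pairs(scf1, max_genes=1)]
        assert pairs
        i, j, _ = pairs[0]
        gained, _, _ = apply_unequal_crossover(scf1, hap2.scaffolds[0], i, j, _UidSource())
        (new_id,) = gained
        gene_ids = [seg.gene.gene_id for seg in scf1.segments if seg.gene is not None]
        k = gene_ids.index(new_id)
        anc = res.truth.ancestor_of
        original = new_id.rsplit(".d", 1)[0]
        # the copy sits immediately next to its template in gene order
        neighbours = gene_ids[max(0, k - 1) : k + 2]
        assert original in neighbours

    def test_mismatched_family_rejected(self):
        res = self._sim_with_tes()
        scf = res.haplotypes[0].scaffolds[0]
        te_idx = [i for i, s in enumerate(scf.segments) if s.kind == "te"]
        fams = {scf.segments[i].family for i in te_idx}
        if len(fams) > 1:
            by_fam = {}
            for i in te_idx:
                by_fam.setdefault(scf.segments[i].family, []).append(i)
            f1, f2 = sorted(by_fam)[:2]
            with pytest.raises(ValueError, match="family"):
                apply_unequal_crossover(
                    scf, res.haplotypes[1].scaffolds[0],
                    min(by_fam[f1][0], by_fam[f2][0]),
                    max(by_fam[f1][0], by_fam[f2][0]),
                    _UidSource(),
                )


class TestRecurrentNahr:
    def test_zero_events_empty_truth(self):
        res = simulate(small_config(n_nahr_events=0))
        assert res.truth.events == []
        assert all(not ivs for ivs in res.truth.nsr_tracts.values())

    def test_same_seed_identical_truth(self):
        cfg = small_config(n_nahr_events=6, te_insertions=60)
        r1, r2 = simulate(cfg), simulate(cfg)
        assert [(e.donor, e.genes_gained) for e in r1.truth.events] == [
            (e.donor, e.genes_gained) for e in r2.truth.events
        ]
        assert {
            s: [(iv.start, iv.end) for iv in ivs] for s, ivs in r1.truth.nsr_tracts.items()
        } == {
            s: [(iv.start, iv.end) for iv in ivs] for s, ivs in r2.truth.nsr_tracts.items()
        }

    def test_copy_number_grows_with_events(self):
        cfg = small_config(genes_per_scaffold=150, te_insertions=150,
                           n_nahr_events=10, nahr_hotspot_bias=100.0)
        res = simulate(cfg)
        assert len(res.truth.events) >= 5
        # replay: every event strictly increases the donor haplotype's copy count
        gains = {"hap1": 0, "hap2": 0}
        for e in res.truth.events:
            assert len(e.genes_gained) >= 1
            gains[e.donor] += len(e.genes_gained)
        total_genes = sum(
            1 for hap in res.haplotypes for s in hap.scaffolds
            for seg in s.segments if seg.kind == "gene"
        )
        total_lost = sum(len(e.genes_lost) for e in res.truth.events)
        assert total_genes == 2 * 150 + sum(gains.values()) - total_lost

    def test_every_gene_traceable_to_ancestor(self):
        res = simulate(small_config(n_nahr_events=8, te_insertions=60))
        ancestors = {f"g0_{i:04d}" for i in range(60)}
        for _, seg in all_genes(res):
            assert res.truth.ancestor_of[seg.gene.gene_id] in ancestors


class TestMutation:
    def test_zero_rates_identical_sequences(self):
        cfg = small_config(background_ks=0.0, background_ka=0.0,
                           dup_ks=0.0, dup_ka=0.0)
        res = simulate(cfg)
        by_anc = {}
        for _, seg in all_genes(res):
            by_anc.setdefault(seg.gene.ancestor_id, []).append(seg.gene.cds)
        for cds_list in by_anc.values():
            assert len(set(cds_list)) == 1

    def test_mutation_never_creates_stop(self):
        res = simulate(small_config(n_nahr_events=5, dup_ks=0.5, dup_ka=0.2))
        for _, seg in all_genes(res):
            cds = seg.gene.cds
            internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)


class TestExpressionSim:
    def test_zero_noise_conserved_pairs_identical(self):
        res = simulate(small_config(expression_noise_sd=0.0))
        by_anc = {}
        for _, seg in all_genes(res):
            if not seg.gene.dup:
                by_anc.setdefault(seg.gene.ancestor_id, []).append(seg.gene.gene_id)
        checked = 0
        for ids in by_anc.values():
            if len(ids) == 2:
                a, b = (res.expression[i] for i in ids)
                np.testing.assert_allclose(a, b)
                checked += 1
        assert checked > 10

    def test_values_non_negative(self):
        res = simulate(small_config())
        assert all((v >= 0).all() for v in res.expression.values())


class TestEmit:
    def test_files_parse_cleanly(self, small_dataset):
        paths = small_dataset["paths"]
        genes = io_formats.read_gff3(paths["hap1_gff"])
        assert genes
        genome = io_formats.read_fasta(paths["hap1_genome"])
        cds = io_formats.read_fasta(paths["hap1_cds"])
        hits = io_formats.read_tabular_hits(paths["hits"])
        reps = io_formats.read_repeatmasker_out(paths["hap1_repeats"])
        expr = io_formats.read_expression_tsv(paths["hap1_expression"])
        assert hits and reps and len(expr) == len(genes)
        # gene intervals point at their CDS in the genome sequence
        for g in genes[:10]:
            seq = genome[g.scaffold_id].residues[g.start : g.end]
            assert seq == cds[g.cds_id].residues

    def test_truth_bed_within_scaffold_bounds(self, small_dataset):
        res = small_dataset["sim"]
        lengths = {
            scf.name: scf.length for hap in res.haplotypes for scf in hap.scaffolds
        }
        for iv in io_formats.read_bed(small_dataset["paths"]["truth_bed"]):
            assert 0 <= iv.start < iv.end <= lengths[iv.scaffold_id]

    def test_zero_event_dataset_gives_zero_nsr(self, tmp_path):
        cfg = SimConfig(seed=19, genes_per_scaffold=300, te_insertions=100,
                        n_nahr_events=0, hotspot_fraction=0.2, n_hotspots=1)
        res = simulate(cfg)
        data = tmp_path / "data"
        emit_dataset(res, data)
        out = run_pipeline(PipelineConfig(data_dir=str(data), out_dir=str(tmp_path / "out")))
        assert out["summary"].genome_fraction_pct == 0.0
        assert out["nsr_intervals"] == []
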