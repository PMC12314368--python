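"""End-to-end orchestration over a dataset directory.

The expected layout is what the simulator emits (and what real data can be
massaged into): per-haplotype ``<hap>.genes.gff3``, ``<hap>.genome.fasta``,
``<hap>.cds.fasta``, optional ``<hap>.expression.tsv`` and
``<hap>.repeats.out``, plus a shared ``hits.tsv``.  Scaffolds are paired
across haplotypes by their order of appearance.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import collinearity as collin
from . import enrichment, expression, genome_qc, io_formats, kaks
from . import nsr_caller as nsr
from .model import GeneModel, Interval


@dataclass(frozen=True)
class PipelineConfig:
    data_dir: str
    out_dir: str
    hap_names: tuple[str, str] = ("hap1", "hap2")
    window: int = 500_000
    step: int = 100_000
    min_genes: int = 15
    max_homolog_frac: float = 0.15
    kaks_threshold: float = 0.3
    kaks_metric: str = "ks"
    collinear: collin.CollinearParams = field(default_factory=collin.CollinearParams)
    max_hits_per_query: int = 5
    seed: int = 0
    import_collinearity: str | None = None  # bypass chaining with native output

    def validate(self) -> None:
        if not Path(self.data_dir).is_dir():
            raise FileNotFoundError(self.data_dir)
        if self.window <= 0 or self.step <= 0 or not (0 < self.max_homolog_frac <= 1):
            raise ValueError("window/step/max_homolog_frac out of range")
        if self.kaks_metric not in kaks.METRICS:
            raise ValueError(f"unknown kaks metric {self.kaks_metric!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cds_of(gene: GeneModel, cds_records) -> str | None:
    for key in (gene.cds_id, gene.gene_id, f"{gene.gene_id}.t1"):
        if key and key in cds_records:
            return cds_records[key].residues
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a result dict (also written as JSON report)."""
    config.validate()
    data = Path(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h1, h2 = config.hap_names

    inputs = {}
    for tag in (h1, h2):
        for suffix in ("genes.gff3", "genome.fasta", "cds.fasta"):
            p = data / f"{tag}.{suffix}"
            if not p.exists():
                raise FileNotFoundError(f"pipeline stage 'io': missing input {p}")
            inputs[f"{tag}.{suffix}"] = p
    hits_path = data / "hits.tsv"
    if not hits_path.exists():
        raise FileNotFoundError(f"pipeline stage 'io': missing input {hits_path}")
    inputs["hits.tsv"] = hits_path

    genes = {t: io_formats.read_gff3(inputs[f"{t}.genes.gff3"], haplotype=t) for t in (h1, h2)}
    genomes = {t: io_formats.read_fasta(inputs[f"{t}.genome.fasta"]) for t in (h1, h2)}
    cds = {t: io_formats.read_fasta(inputs[f"{t}.cds.fasta"]) for t in (h1, h2)}
    hits = io_formats.read_tabular_hits(hits_path, config.max_hits_per_query)

    # --- genome QC + Ref/Alt assignment (scaffolds paired by order) -------
    scaffold_order = {
        t: [s for s in dict.fromkeys(g.scaffold_id for g in genes[t])] for t in (h1, h2)
    }
    assignments = []
    telomere_rows, gap_rows = [], []
    for s1, s2 in zip(scaffold_order[h1], scaffold_order[h2]):
        info1 = genome_qc.scaffold_info(genomes[h1][s1])
        info2 = genome_qc.scaffold_info(genomes[h2][s2])
        assignments.append(genome_qc.assign_ref_alt(info1, info2))
        for t, s in ((h1, s1), (h2, s2)):
            for arr in genome_qc.find_telomere_arrays(genomes[t][s]):
                telomere_rows.append((s, arr.start, arr.end, arr.scaffold_end, arr.motif_copies, arr.strand))
            for gap in genome_qc.count_gap_runs(genomes[t][s]):
                gap_rows.append((s, gap.start, gap.end))
    pd.DataFrame(
        [(a.ref_id, a.alt_id, a.rule_used) for a in assignments],
        columns=["ref_scaffold", "alt_scaffold", "rule"],
    ).to_csv(out / "haplotype_assignment.tsv", sep="\t", index=False)
    io_formats.write_bed(
        [Interval(s, a, b, lab, float(c), st) for s, a, b, lab, c, st in telomere_rows],
        out / "telomeres.bed",
    )
    io_formats.write_bed([Interval(s, a, b, "gap") for s, a, b in gap_rows], out / "gaps.bed")

    # --- collinearity + Ka/Ks + homolog flags -----------------------------
    genes_by_scaffold = {
        t: {s: [g for g in genes[t] if g.scaffold_id == s] for s in scaffold_order[t]}
        for t in (h1, h2)
    }
    all_blocks = []
    kaks_rows = []
    flags: dict[str, bool] = {}
    if config.import_collinearity:
        all_blocks = io_formats.read_mcscanx_collinearity(config.import_collinearity)
    for s1, s2 in zip(scaffold_order[h1], scaffold_order[h2]):
        ga = genes_by_scaffold[h1][s1]
        gb = genes_by_scaffold[h2][s2]
        ids_a = {g.gene_id for g in ga}
        ids_b = {g.gene_id for g in gb}
        pair_hits = [
            h for h in hits if h.query_id in ids_a and h.subject_id in ids_b
        ]
        if config.import_collinearity:
            blocks = [
                b
                for b in all_blocks
                if {a.gene_a for a in b.anchors} & ids_a or b.scaffold_a == s1
            ]
        else:
            anchors = collin.build_anchors(pair_hits, ga, gb, config.collinear.e_value_cut)
            blocks = collin.chain_anchors(
                anchors, config.collinear, len(ga), len(gb), s1, s2
            )
            all_blocks.extend(blocks)
        kaks_results = {}
        cds_a, cds_b = cds[h1], cds[h2]
        gene_index = {g.gene_id: g for g in ga + gb}
        for block in blocks:
            for a in block.anchors:
                key = (a.gene_a, a.gene_b)
                if key in kaks_results:
                    continue
                seq_a = _cds_of(gene_index[a.gene_a], cds_a)
                seq_b = _cds_of(gene_index[a.gene_b], cds_b)
                if seq_a is None or seq_b is None:
                    raise KeyError(f"stage 'kaks': missing CDS for pair {key}")
                res = kaks.kaks_from_cds(seq_a, seq_b)
                kaks_results[key] = res
                kaks_rows.append(
                    (a.gene_a, a.gene_b, res.S, res.N, res.sd, res.nd, res.Ka, res.Ks,
                     res.ratio, kaks.classify_homologous(res, config.kaks_threshold, config.kaks_metric))
                )
        flags.update(
            collin.homologous_gene_flags(
                blocks, kaks_results, config.kaks_threshold, config.kaks_metric
            )
        )
    io_formats.write_mcscanx_collinearity(all_blocks, out / "blocks.collinearity")
    pd.DataFrame(
        kaks_rows,
        columns=["gene_a", "gene_b", "S", "N", "sd", "nd", "Ka", "Ks", "ratio", "is_homologous"],
    ).to_csv(out / "kaks.tsv", sep="\t", index=False)

    # --- window scan + nSR calling ----------------------------------------
    window_rows = []
    nsr_intervals: list[nsr.NSRInterval] = []
    for t in (h1, h2):
        for s in scaffold_order[t]:
            glist = genes_by_scaffold[t][s]
            scaffold_len = len(genomes[t][s])
            calls = nsr.call_windows(
                glist, flags, scaffold_len,
                window=config.window, step=config.step,
                min_genes=config.min_genes, max_homolog_frac=config.max_homolog_frac,
            )
            for w in calls:
                window_rows.append(
                    (w.scaffold_id, w.start, w.end, w.n_genes, w.n_homologous, w.label, w.is_tail)
                )
            nsr_intervals.extend(nsr.merge_nsr(calls))
    pd.DataFrame(
        window_rows,
        columns=["scaffold", "start", "end", "n_genes", "n_homologous", "label", "is_tail"],
    ).to_csv(out / "windows.tsv", sep="\t", index=False)
    io_formats.write_bed(nsr.nsr_to_intervals(nsr_intervals), out / "nsr.bed")

    scaffold_lengths = {
        s: len(genomes[t][s]) for t in (h1, h2) for s in scaffold_order[t]
    }
    all_genes = genes[h1] + genes[h2]
    summary = nsr.summarize_nsr(nsr_intervals, scaffold_lengths, {"all_genes": all_genes})
    with open(out / "nsr_summary.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"genome_span_bp\t{summary.genome_span}\n")
        fh.write(f"genome_length_bp\t{summary.genome_length}\n")
        fh.write(f"genome_fraction_pct\t{summary.genome_fraction_pct}\n")
        for gs in summary.gene_sets:
            fh.write(f"{gs.set_name}_in_nsr\t{gs.n_in_nsr}\n")
            fh.write(f"{gs.set_name}_total\t{gs.n_total}\n")
            fh.write(f"{gs.set_name}_pct\t{gs.pct_in_nsr}\n")

    # --- TE enrichment in nSRs --------------------------------------------
    nsr_by_scaffold: dict[str, list[nsr.NSRInterval]] = {}
    for iv in nsr_intervals:
        nsr_by_scaffold.setdefault(iv.scaffold_id, []).append(iv)
    for ivs in nsr_by_scaffold.values():
        ivs.sort(key=lambda x: x.start)

    def _in_nsr(scaffold: str, midpoint: int) -> bool:
        probe = GeneModel("_probe", scaffold, midpoint, midpoint + 1, "+")
        ivs = nsr_by_scaffold.get(scaffold, [])
        return bool(ivs) and nsr.classify_gene_region(probe, ivs) == "nSR"

    feature_map: dict[str, list[str]] = {}
    in_nsr_flag: dict[str, bool] = {}
    for g in all_genes:
        feature_map[g.gene_id] = ["protein_coding"]
        in_nsr_flag[g.gene_id] = _in_nsr(g.scaffold_id, g.midpoint)
    n_te = 0
    for t in (h1, h2):
        rp = data / f"{t}.repeats.out"
        if not rp.exists():
            continue
        for r in io_formats.read_repeatmasker_out(rp):
            item = f"te:{t}:{n_te}"
            n_te += 1
            feature_map[item] = [f"TE:{r.family}"]
            in_nsr_flag[item] = _in_nsr(r.scaffold_id, r.midpoint)
    enrich_results = [
        r
        for r in enrichment.enrich_features(feature_map, in_nsr_flag, tail="upper")
        if str(r.feature_id).startswith("TE:")
    ]
    pd.DataFrame(
        [(r.feature_id, r.k, r.n, r.K, r.N, r.p_enrich, r.p_deplete, r.q) for r in enrich_results],
        columns=["feature", "k", "n", "K", "N", "p_enrich", "p_deplete", "q"],
    ).to_csv(out / "te_enrichment.tsv", sep="\t", index=False)

    # --- expression correlation contrast (optional stage) ------------------
    expr_summary = None
    e1, e2 = data / f"{h1}.expression.tsv", data / f"{h2}.expression.tsv"
    if e1.exists() and e2.exists():
        mat1 = io_formats.read_expression_tsv(e1)
        mat2 = io_formats.read_expression_tsv(e2)
        gene_index_all = {g.gene_id: g for g in all_genes}
        pairs, regions = [], {}
        seen = set()
        for h in hits:
            a, b = h.query_id, h.subject_id
            if a in mat1.index and b in mat2.index:
                key = (a, b)
                if key in seen or (b, a) in seen:
                    continue
                seen.add(key)
                ga, gb = gene_index_all.get(a), gene_index_all.get(b)
                if ga is None or gb is None:
                    continue
                in_a = _in_nsr(ga.scaffold_id, ga.midpoint)
                in_b = _in_nsr(gb.scaffold_id, gb.midpoint)
                pairs.append(key)
                regions[key] = "nSR" if (in_a or in_b) else "SR"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            corrs = expression.pair_correlations(pairs, mat1, mat2, regions)
        pd.DataFrame(
            [(c.gene_a, c.gene_b, c.r, c.n_stages, c.region) for c in corrs],
            columns=["gene_a", "gene_b", "r", "n_stages", "region"],
        ).to_csv(out / "expression_correlation.tsv", sep="\t", index=False)
        expr_summary = expression.summarize_mean_r(corrs)
    else:
        warnings.warn("expression matrices missing; expression stage skipped")

    # --- manifest ----------------------------------------------------------
    manifest = {
        "parameters": {
            **{k: v for k, v in asdict(config).items() if k != "collinear"},
            "collinear": asdict(config.collinear),
        },
        "inputs": {name: _sha256(p) for name, p in sorted(inputs.items())},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "n_blocks": len(all_blocks),
        "n_homologous_genes": sum(1 for v in flags.values() if v),
        "nsr_intervals": nsr_intervals,
        "summary": summary,
        "te_enrichment": enrich_results,
        "expression_summary": expr_summary,
        "assignments": assignments,
        "flags": flags,
        "out_dir": str(out),
    }
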