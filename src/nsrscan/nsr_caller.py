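"""Sliding-window calling of non-syntenic regions (nSRs) and summaries.

A window is non-syntenic when it holds at least ``min_genes`` genes (the
"more than 14" rule, i.e. >= 15 by default) of which strictly less than
``max_homolog_frac`` (15%) are flagged homologous.  Genes are assigned to
windows by midpoint.  Windows slide at ``step`` over each scaffold, plus one
right-aligned tail window so chromosome ends are evaluable.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import GeneModel, Interval

LABELS = ("syntenic", "non_syntenic", "undetermined")


@dataclass(frozen=True, slots=True)
class WindowCall:
    scaffold_id: str
    start: int
    end: int
    n_genes: int
    n_homologous: int
    label: str
    is_tail: bool = False
    whole_scaffold: bool = False

    @property
    def homolog_fraction(self) -> float:
        return self.n_homologous / self.n_genes if self.n_genes else math.nan


@dataclass(frozen=True, slots=True)
class NSRInterval:
    scaffold_id: str
    start: int
    end: int
    pairing: str = "hap_vs_hap"  # or species_vs_species


@dataclass(frozen=True, slots=True)
class GeneSetSummary:
    set_name: str
    n_in_nsr: int
    n_total: int
    pct_in_nsr: float


@dataclass(frozen=True, slots=True)
class NSRSummary:
    per_scaffold_span: dict
    per_scaffold_fraction: dict
    genome_span: int | float
    genome_length: int | float
    genome_fraction_pct: float
    gene_sets: tuple[GeneSetSummary, ...] = ()


def report_pct(numerator: float, denominator: float) -> float:
    """Percentage truncated (not rounded) to one decimal.

    Truncation matches the reporting convention of the source counts this
    toolkit reproduces (e.g. 105/1794 -> 5.8, not 5.9).
    """
    if denominator <= 0:
        return 0.0
    frac = numerator / denominator
    return math.floor(frac * 1000.0 + 1e-9) / 10.0


def call_windows(
    genes: Sequence[GeneModel],
    flags: Mapping[str, bool],
    scaffold_len: int,
    window: int = 500_000,
    step: int = 100_000,
    min_genes: int = 15,
    max_homolog_frac: float = 0.15,
) -> list[WindowCall]:
    """Classify sliding windows on one scaffold.

    ``flags`` maps gene_id -> homologous?; genes absent from the mapping are
    non-homologous.  Labels: non_syntenic iff n_genes >= min_genes and
    homolog fraction < max_homolog_frac (strict); fewer genes -> syntenic;
    zero genes -> undetermined.
    """
    if scaffold_len <= 0:
        raise ValueError("scaffold_len must be positive")
    scaffolds = {g.scaffold_id for g in genes}
    if len(scaffolds) > 1:
        raise ValueError(f"genes span multiple scaffolds: {sorted(scaffolds)}")
    scaffold_id = genes[0].scaffold_id if genes else ""

    mids = sorted(g.midpoint for g in genes)
    hom_mids = sorted(g.midpoint for g in genes if flags.get(g.gene_id, False))

    def _call(start: int, end: int, is_tail: bool, whole: bool) -> WindowCall:
        n = bisect_right(mids, end - 1) - bisect_right(mids, start - 1)
        h = bisect_right(hom_mids, end - 1) - bisect_right(hom_mids, start - 1)
        if n == 0:
            label = "undetermined"
        elif n >= min_genes and h / n < max_homolog_frac:
            label = "non_syntenic"
        else:
            label = "syntenic"
        return WindowCall(scaffold_id, start, end, n, h, label, is_tail, whole)

    calls: list[WindowCall] = []
    if scaffold_len < window:
        calls.append(_call(0, scaffold_len, False, True))
        return calls
    starts = list(range(0, scaffold_len - window + 1, step))
    for s in starts:
        calls.append(_call(s, s + window, False, False))
    tail_start = scaffold_len - window
    if tail_start not in starts:
        calls.append(_call(tail_start, scaffold_len, True, False))
    return calls


def merge_nsr(
    window_calls: Iterable[WindowCall], pairing: str = "hap_vs_hap"
) -> list[NSRInterval]:
    """Union of all non-syntenic windows of one scaffold, merged when
    overlapping or exactly adjacent."""
    flagged = [w for w in window_calls if w.label == "non_syntenic"]
    if not flagged:
        return []
    scaffolds = {w.scaffold_id for w in flagged}
    if len(scaffolds) > 1:
        raise ValueError(f"window calls from multiple scaffolds: {sorted(scaffolds)}")
    scaffold_id = flagged[0].scaffold_id
    spans = sorted((w.start, w.end) for w in flagged)
    merged: list[list[int]] = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [NSRInterval(scaffold_id, s, e, pairing) for s, e in merged]


def classify_gene_region(
    gene: GeneModel, nsr_intervals: Sequence[NSRInterval]
) -> str:
    """'nSR' iff the gene midpoint lies in a (sorted, disjoint) interval."""
    mid = gene.midpoint
    starts = [iv.start for iv in nsr_intervals]
    i = bisect_right(starts, mid) - 1
    if i >= 0 and nsr_intervals[i].start <= mid < nsr_intervals[i].end:
        return "nSR"
    return "syntenic_region"


def summarize_nsr(
    nsr_intervals: Sequence[NSRInterval],
    scaffold_lengths: Mapping[str, float],
    gene_sets: Mapping[str, Sequence[GeneModel]] | None = None,
) -> NSRSummary:
    """Genome-level nSR spans, fractions (% truncated to one decimal), and
    per-gene-set membership counts (midpoint containment)."""
    by_scaffold: dict[str, list[NSRInterval]] = {}
    for iv in nsr_intervals:
        by_scaffold.setdefault(iv.scaffold_id, []).append(iv)
    span: dict[str, float] = {}
    frac: dict[str, float] = {}
    for scf, ivs in by_scaffold.items():
        ivs.sort(key=lambda x: x.start)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                raise ValueError(f"overlapping nSR intervals on {scf}")
        total = sum(iv.end - iv.start for iv in ivs)
        if scf not in scaffold_lengths:
            raise ValueError(f"no length for scaffold {scf}")
        if total > scaffold_lengths[scf]:
            raise ValueError(f"nSR span exceeds scaffold length on {scf}")
        span[scf] = total
        frac[scf] = report_pct(total, scaffold_lengths[scf])
    genome_span = sum(span.values())
    genome_len = sum(scaffold_lengths.values())
    set_summaries: list[GeneSetSummary] = []
    if gene_sets:
        for name, genes in gene_sets.items():
            n_in = 0
            for g in genes:
                ivs = by_scaffold.get(g.scaffold_id, [])
                if ivs and classify_gene_region(g, ivs) == "nSR":
                    n_in += 1
            set_summaries.append(
                GeneSetSummary(name, n_in, len(genes), report_pct(n_in, len(genes)))
            )
    return NSRSummary(
        per_scaffold_span=span,
        per_scaffold_fraction=frac,
        genome_span=genome_span,
        genome_length=genome_len,
        genome_fraction_pct=report_pct(genome_span, genome_len),
        gene_sets=tuple(set_summaries),
    )


def nsr_to_intervals(nsrs: Sequence[NSRInterval]) -> list[Interval]:
    return [Interval(iv.scaffold_id, iv.start, iv.end, iv.pairing) for iv in nsrs]
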