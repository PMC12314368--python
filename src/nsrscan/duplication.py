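"""Tandem-duplicate (TDG) and species-specific tandem-duplicate (SSTDG)
classification from gene order and orthogroup membership.

A TDG pair is two same-orthogroup genes on one scaffold that are adjacent in
gene rank, or separated by exactly one gene belonging to a different group.
An SSTDG is an orthogroup in which one species carries a single copy in each
haplotype and the other exactly two per haplotype, with the two copies
tandemly arranged in at least one haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import GeneModel, HitRecord
from .nsr_caller import NSRInterval, classify_gene_region, report_pct


@dataclass(frozen=True, slots=True)
class OrthoGroup:
    group_id: str
    members: tuple[str, ...]  # gene ids

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.group_id}: no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"orthogroup {self.group_id}: duplicate members")


@dataclass(frozen=True, slots=True)
class TDGPair:
    gene_a: str
    gene_b: str
    scaffold_id: str
    intervening_unrelated: int  # 0 or 1

    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass(frozen=True, slots=True)
class SSTDGCall:
    group_id: str
    expanded_species: str
    copy_numbers: tuple  # ((species, haplotype, count), ...)
    pair: TDGPair


# ---------------------------------------------------------------------------
# Orthogroup input / fallback clustering
# ---------------------------------------------------------------------------

def read_orthogroups(path) -> list[OrthoGroup]:
    """Read an orthoMCL-style cluster file: ``group_id: sp|gene sp|gene ...``.

    The species tag before ``|`` is stripped; gene ids must be globally
    unique across species in this toolkit.
    """
    groups: list[OrthoGroup] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line:
                gid, rest = line.split(":", 1)
            else:
                gid, rest = f"group{lineno}", line
            members = tuple(
                tok.split("|", 1)[1] if "|" in tok else tok for tok in rest.split()
            )
            groups.append(OrthoGroup(gid.strip(), members))
    return groups


def write_orthogroups(groups: Iterable[OrthoGroup], species_of: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for g in groups:
            toks = " ".join(f"{species_of.get(m, 'sp')}|{m}" for m in g.members)
            fh.write(f"{g.group_id}: {toks}\n")


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_orthogroups_fallback(
    hits: Sequence[HitRecord],
    genome_of: Mapping[str, str],
    e_value_cut: float = 1e-5,
) -> list[OrthoGroup]:
    """Lightweight orthogroup stand-in: connected components of the
    reciprocal-best-hit graph between genomes, augmented by within-genome
    hits passing the e-value cut.

    ``genome_of`` maps gene_id -> genome label (species+haplotype).  Genes
    named in the mapping but hit by nothing form singleton groups.
    """
    best: dict[tuple[str, str], tuple[float, str]] = {}  # (query, target genome) -> (bits, subject)
    within: list[tuple[str, str]] = []
    for h in hits:
        if h.e_value > e_value_cut:
            continue
        gq, gs = genome_of[h.query_id], genome_of[h.subject_id]
        if gq == gs:
            within.append((h.query_id, h.subject_id))
            continue
        key = (h.query_id, gs)
        cur = best.get(key)
        cand = (h.bit_score, h.subject_id)
        # higher bit score wins; ties by lexicographic subject id
        if cur is None or cand[0] > cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
            best[key] = cand
    dsu = _DSU(genome_of.keys())
    for (q, gs), (_, s) in best.items():
        back = best.get((s, genome_of[q]))
        if back is not None and back[1] == q:
            dsu.union(q, s)
    for q, s in within:
        dsu.union(q, s)
    comps: dict[str, list[str]] = {}
    for gene in genome_of:
        comps.setdefault(dsu.find(gene), []).append(gene)
    groups = [
        OrthoGroup(f"OG{i:05d}", tuple(sorted(members)))
        for i, (_, members) in enumerate(
            sorted(comps.items(), key=lambda kv: sorted(kv[1])[0])
        )
    ]
    return groups


# ---------------------------------------------------------------------------
# TDG / SSTDG
# ---------------------------------------------------------------------------

def find_tdg_pairs(
    genes: Sequence[GeneModel],
    group_of: Mapping[str, str],
) -> list[TDGPair]:
    """All same-orthogroup pairs at rank distance 1, or distance 2 with the
    intervening gene in a different group.  ``genes`` may span scaffolds;
    ranks are computed per scaffold by start position."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    pairs: list[TDGPair] = []
    for scf, glist in sorted(by_scaffold.items()):
        glist.sort(key=lambda g: (g.start, g.gene_id))
        for i, gi in enumerate(glist):
            grp = group_of.get(gi.gene_id)
            if grp is None:
                continue
            for dist in (1, 2):
                j = i + dist
                if j >= len(glist):
                    break
                gj = glist[j]
                if group_of.get(gj.gene_id) != grp:
                    continue
                if dist == 2 and group_of.get(glist[i + 1].gene_id) == grp:
                    continue  # intervening gene is related
                pairs.append(TDGPair(gi.gene_id, gj.gene_id, scf, dist - 1))
    return pairs


def call_sstdg(
    orthogroups: Sequence[OrthoGroup],
    tdg_pairs: Sequence[TDGPair],
    gene_tags: Mapping[str, tuple[str, str]],
    species_pair: tuple[str, str],
) -> list[SSTDGCall]:
    """Species-specific tandem duplications.

    ``gene_tags`` maps gene_id -> (species, haplotype).  A group qualifies
    when one species of ``species_pair`` has exactly 1 copy in each of its
    two haplotypes, the other exactly 2 in each, and the duplicated species'
    two copies form a TDG pair in at least one haplotype.
    """
    pair_index: dict[frozenset, TDGPair] = {p.key(): p for p in tdg_pairs}
    sp_x, sp_y = species_pair
    calls: list[SSTDGCall] = []
    for grp in orthogroups:
        counts: dict[tuple[str, str], list[str]] = {}
        for m in grp.members:
            tag = gene_tags.get(m)
            if tag is None:
                continue
            counts.setdefault(tag, []).append(m)
        for single, doubled in ((sp_x, sp_y), (sp_y, sp_x)):
            haps_s = sorted(h for (sp, h) in counts if sp == single)
            haps_d = sorted(h for (sp, h) in counts if sp == doubled)
            if len(set(haps_s)) != 2 or len(set(haps_d)) != 2:
                continue
            if not all(len(counts[(single, h)]) == 1 for h in set(haps_s)):
                continue
            if not all(len(counts[(doubled, h)]) == 2 for h in set(haps_d)):
                continue
            tandem_pair = None
            for h in sorted(set(haps_d)):
                key = frozenset(counts[(doubled, h)])
                if key in pair_index:
                    tandem_pair = pair_index[key]
                    break
            if tandem_pair is None:
                continue
            copy_numbers = tuple(
                sorted((sp, h, len(v)) for (sp, h), v in counts.items())
            )
            calls.append(SSTDGCall(grp.group_id, doubled, copy_numbers, tandem_pair))
            break
    return calls


def sstdg_nsr_overlap(
    calls: Sequence[SSTDGCall],
    nsr_intervals: Sequence[NSRInterval],
    gene_coords: Mapping[str, GeneModel],
) -> tuple[int, int, float]:
    """(n_in_nsr, n_total, percentage) of SSTDGs whose duplicated-pair span
    midpoint falls inside an nSR interval."""
    by_scaffold: dict[str, list[NSRInterval]] = {}
    for iv in nsr_intervals:
        by_scaffold.setdefault(iv.scaffold_id, []).append(iv)
    for ivs in by_scaffold.values():
        ivs.sort(key=lambda x: x.start)
    n_in = 0
    for call in calls:
        ga = gene_coords[call.pair.gene_a]
        gb = gene_coords[call.pair.gene_b]
        span_start = min(ga.start, gb.start)
        span_end = max(ga.end, gb.end)
        probe = GeneModel(
            gene_id="_probe",
            scaffold_id=call.pair.scaffold_id,
            start=span_start,
            end=span_end,
            strand="+",
        )
        ivs = by_scaffold.get(call.pair.scaffold_id, [])
        if ivs and classify_gene_region(probe, ivs) == "nSR":
            n_in += 1
    return n_in, len(calls), report_pct(n_in, len(calls))
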