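"""Forward simulator of a haplotype pair diverging by transposon-mediated
unequal crossing over, emitting every pipeline input plus ground truth.

The genome is an ordered list of segments per scaffold (genes, transposon
copies, intergenic DNA, telomere arrays, assembly gaps); coordinates are
derived from cumulative segment lengths, so duplications and deletions are
list splices and never go out of register.  Each segment carries an
``origin`` lineage id: copies produced by an unequal-crossover event share
the origin of their template, which is what makes every post-simulation
gene traceable to exactly one ancestral gene.

Recombination mechanics: an event picks two same-family transposon copies
flanking a small tract on the donor haplotype.  The donor gains a tandem
copy of the tract (plus a recombinant transposon copy, which fuels further
events); the receiver haplotype loses one copy of each tract segment.
Events are biased into a configurable number of interior "hotspot" tracts;
hotspots that received at least one event are recorded, at their final
coordinates, as the true disordered tracts.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .kaks import CODON_TABLE, NT, SENSE_CODONS, STOP_CODONS
from .model import GeneModel, HitRecord, Interval, RepeatAnnotation, SequenceRecord

TE_FAMILIES = ("Copia-like", "Sola3-like", "L1-like", "Maverick-like")
TE_CLASSES = {"Copia-like": "LTR", "Sola3-like": "DNA", "L1-like": "LINE", "Maverick-like": "DNA"}
TELOMERE_MOTIF = "TTAGGG"
STAGES = ("egg", "donut", "prawnchip", "preplanula", "planula", "polyp", "adult")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    species: str = "simsp"
    n_scaffolds: int = 1
    genes_per_scaffold: int = 400
    gene_len_range: tuple[int, int] = (300, 900)  # rounded to codons
    intergenic_len_range: tuple[int, int] = (1000, 3000)
    te_insertions: int = 150  # insertion events per haplotype
    te_len: int = 400
    te_hotspot_bias: float = 10.0
    n_hotspots: int = 3
    hotspot_fraction: float = 0.15
    n_nahr_events: int = 0
    nahr_hotspot_bias: float = 50.0
    tract_max_genes: int = 5
    background_ks: float = 0.02
    background_ka: float = 0.005
    dup_ks: float = 0.35
    dup_ka: float = 0.10
    expression_noise_sd: float = 0.1
    telomere_copies: int = 60
    gap_runs_hap1: int = 2
    gap_runs_hap2: int = 4
    gap_len: int = 100

    def __post_init__(self) -> None:
        if min(self.background_ks, self.background_ka, self.dup_ks, self.dup_ka) < 0:
            raise ValueError("substitution rates must be >= 0")
        if self.dup_ks < self.background_ks or self.dup_ka < self.background_ka:
            raise ValueError("duplicate-tract rates must be >= background rates")
        if not (0 <= self.hotspot_fraction < 1):
            raise ValueError("hotspot_fraction must be in [0, 1)")


@dataclass
class SimGene:
    gene_id: str
    ancestor_id: str
    cds: str  # includes terminal stop codon
    dup: bool = False


@dataclass
class Segment:
    kind: str  # intergenic | te | gene | telomere | gap
    uid: int
    origin: int
    seq: str = ""
    gene: SimGene | None = None
    family: str | None = None
    hotspot: int = -1
    dup: bool = False

    @property
    def length(self) -> int:
        return len(self.gene.cds) if self.kind == "gene" else len(self.seq)


@dataclass
class Scaffold:
    name: str
    segments: list[Segment]

    def coordinates(self) -> list[tuple[int, int]]:
        out = []
        pos = 0
        for seg in self.segments:
            out.append((pos, pos + seg.length))
            pos += seg.length
        return out

    @property
    def length(self) -> int:
        return sum(seg.length for seg in self.segments)


@dataclass
class Haplotype:
    name: str  # hap1 / hap2
    scaffolds: list[Scaffold]


@dataclass(frozen=True)
class NahrEvent:
    event_id: int
    scaffold_index: int
    donor: str
    receiver: str
    family: str
    hotspot: int
    genes_gained: tuple[str, ...]
    genes_lost: tuple[str, ...]
    donor_interval: tuple[int, int]  # donor coords at event time


@dataclass
class SimTruth:
    events: list[NahrEvent]
    nsr_tracts: dict[str, list[Interval]]  # scaffold name -> truth intervals
    ancestor_of: dict[str, str]  # gene id -> ancestral gene id
    dup_genes: set[str]  # gene ids with elevated divergence

    def pair_label(self, gene_a: str, gene_b: str) -> str:
        """'ortholog' for conserved 1:1 descendants, 'paralog' when either
        side sits in a duplicated/disordered tract, 'unrelated' otherwise."""
        anc_a, anc_b = self.ancestor_of.get(gene_a), self.ancestor_of.get(gene_b)
        if anc_a is None or anc_b is None or anc_a != anc_b:
            return "unrelated"
        if gene_a in self.dup_genes or gene_b in self.dup_genes:
            return "paralog"
        return "ortholog"


@dataclass
class SimResult:
    config: SimConfig
    haplotypes: tuple[Haplotype, Haplotype]
    truth: SimTruth
    expression: dict[str, "np.ndarray"] = field(default_factory=dict)

    def genes(self, hap: Haplotype):
        for scf in hap.scaffolds:
            coords = scf.coordinates()
            for seg, (s, e) in zip(scf.segments, coords):
                if seg.kind == "gene":
                    yield scf, seg, s, e


# ---------------------------------------------------------------------------
# Random sequence helpers
# ---------------------------------------------------------------------------

_NT_ARR = np.array(list(NT))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT_ARR[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; length 3*(n_codons+2)."""
    body = rng.choice(len(SENSE_CODONS), n_codons)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _te_seq(rng: np.random.Generator, family: str, length: int) -> str:
    """Family-tagged synthetic repeat: a family-specific 20-mer core tandemly
    repeated with light random decoration."""
    core_rng = np.random.Generator(np.random.PCG64(zlib.crc32(family.encode())))
    core = _random_dna(core_rng, 20)
    reps = length // 20 + 1
    seq = list((core * reps)[:length])
    for i in rng.integers(0, length, max(1, length // 50)):
        seq[i] = NT[rng.integers(0, 4)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Stage 1: ancestor and haplotype duplication
# ---------------------------------------------------------------------------

class _UidSource:
    def __init__(self) -> None:
        self._counter = itertools.count()

    def __call__(self) -> int:
        return next(self._counter)


def simulate_ancestor(config: SimConfig, rng: np.random.Generator, uid: _UidSource) -> list[Scaffold]:
    """Build the ancestral (haploid) genome with hotspot tracts marked."""
    scaffolds: list[Scaffold] = []
    for k in range(config.n_scaffolds):
        n_genes = config.genes_per_scaffold
        # interior hotspot gene ranges, evenly spaced between 15% and 85%
        hotspot_genes: dict[int, int] = {}
        if config.n_hotspots > 0 and config.hotspot_fraction > 0:
            per_hotspot = max(1, round(config.hotspot_fraction * n_genes / config.n_hotspots))
            lo, hi = int(0.15 * n_genes), int(0.85 * n_genes)
            usable = hi - lo
            if per_hotspot * config.n_hotspots > usable:
                raise ValueError("hotspot tracts exceed interior gene capacity")
            slot = usable // config.n_hotspots
            for h in range(config.n_hotspots):
                start = lo + h * slot + (slot - per_hotspot) // 2
                for g in range(start, start + per_hotspot):
                    hotspot_genes[g] = h + k * config.n_hotspots
        segments: list[Segment] = []
        for g in range(n_genes):
            ig_len = int(rng.integers(*config.intergenic_len_range))
            # intergenic inherits a hotspot only when both flanking genes share it
            hs_prev = hotspot_genes.get(g - 1, -1)
            hs_next = hotspot_genes.get(g, -1)
            hs = hs_next if hs_prev == hs_next else -1
            segments.append(Segment("intergenic", uid(), uid(), seq=_random_dna(rng, ig_len), hotspot=hs))
            n_codons = int(rng.integers(config.gene_len_range[0] // 3, config.gene_len_range[1] // 3))
            gene_id = f"g{k}_{g:04d}"
            gene = SimGene(gene_id, gene_id, _random_cds(rng, n_codons))
            segments.append(
                Segment("gene", uid(), uid(), gene=gene, hotspot=hotspot_genes.get(g, -1))
            )
        segments.append(Segment("intergenic", uid(), uid(), seq=_random_dna(rng, int(rng.integers(*config.intergenic_len_range)))))
        scaffolds.append(Scaffold(f"scf{k}", segments))
    return scaffolds


def _copy_to_haplotype(
    ancestor: list[Scaffold], hap_name: str, config: SimConfig, uid: _UidSource
) -> Haplotype:
    scaffolds = []
    for scf in ancestor:
        segs = []
        for seg in scf.segments:
            gene = None
            if seg.gene is not None:
                gid = f"{config.species}_{hap_name}_{seg.gene.gene_id}"
                gene = SimGene(gid, seg.gene.gene_id, seg.gene.cds)
            segs.append(
                Segment(seg.kind, uid(), seg.origin, seq=seg.seq, gene=gene,
                        family=seg.family, hotspot=seg.hotspot)
            )
        scaffolds.append(Scaffold(f"{config.species}_{hap_name}_{scf.name}", segs))
    return Haplotype(hap_name, scaffolds)


# ---------------------------------------------------------------------------
# Stage 2: transposons
# ---------------------------------------------------------------------------

def insert_transposons(hap: Haplotype, config: SimConfig, rng: np.random.Generator, uid: _UidSource) -> None:
    """Insert TE copies at intergenic positions, biased into hotspots."""
    if config.te_insertions <= 0:
        return
    for _ in range(config.te_insertions):
        # choose a scaffold, then an intergenic segment weighted by hotspot bias
        scf = hap.scaffolds[int(rng.integers(0, len(hap.scaffolds)))]
        candidates = [i for i, s in enumerate(scf.segments) if s.kind == "intergenic"]
        weights = np.array(
            [config.te_hotspot_bias if scf.segments[i].hotspot >= 0 else 1.0 for i in candidates]
        )
        weights /= weights.sum()
        idx = int(rng.choice(len(candidates), p=weights))
        seg_idx = candidates[idx]
        host = scf.segments[seg_idx]
        family = TE_FAMILIES[int(rng.integers(0, len(TE_FAMILIES)))]
        cut = int(rng.integers(0, len(host.seq) + 1)) if host.seq else 0
        left = Segment("intergenic", uid(), uid(), seq=host.seq[:cut], hotspot=host.hotspot)
        te = Segment("te", uid(), uid(), seq=_te_seq(rng, family, config.te_len),
                     family=family, hotspot=host.hotspot)
        right = Segment("intergenic", uid(), uid(), seq=host.seq[cut:], hotspot=host.hotspot)
        scf.segments[seg_idx : seg_idx + 1] = [s for s in (left, te, right) if s.length > 0 or s.kind == "te"]


# ---------------------------------------------------------------------------
# Stage 3: unequal crossing over
# ---------------------------------------------------------------------------

_dup_counter = itertools.count(1)


def apply_unequal_crossover(
    donor_scf: Scaffold,
    receiver_scf: Scaffold,
    te_i: int,
    te_j: int,
    uid: _UidSource,
) -> tuple[tuple[str, ...], tuple[str, ...], tuple[int, int]] | None:
    """One unequal-crossover event between two same-family TE copies.

    The tract strictly between segment indices ``te_i`` and ``te_j`` on the
    donor is tandemly duplicated there (plus a recombinant TE copy) and one
    copy of each tract segment lineage is deleted from the receiver.
    Returns (genes_gained, genes_lost, donor_interval) or None for an empty
    tract (no-op).
    """
    a, b = donor_scf.segments[te_i], donor_scf.segments[te_j]
    if a.kind != "te" or b.kind != "te":
        raise ValueError("crossover sites must be transposon segments")
    if a.family != b.family:
        raise ValueError("crossover sites must share a transposon family")
    tract = donor_scf.segments[te_i + 1 : te_j]
    if not tract:
        return None

    gained: list[str] = []
    new_segments: list[Segment] = []
    # recombinant TE copy heads the duplicated tract
    new_segments.append(
        Segment("te", uid(), a.origin, seq=a.seq, family=a.family, hotspot=a.hotspot, dup=True)
    )
    for seg in tract:
        seg.dup = True
        if seg.gene is not None:
            seg.gene.dup = True
            new_gene_id = f"{seg.gene.gene_id}.d{next(_dup_counter)}"
            gene = SimGene(new_gene_id, seg.gene.ancestor_id, seg.gene.cds, dup=True)
            gained.append(new_gene_id)
            new_segments.append(
                Segment("gene", uid(), seg.origin, gene=gene, hotspot=seg.hotspot, dup=True)
            )
        else:
            new_segments.append(
                Segment(seg.kind, uid(), seg.origin, seq=seg.seq, family=seg.family,
                        hotspot=seg.hotspot, dup=True)
            )
    coords = donor_scf.coordinates()
    donor_interval = (coords[te_i][0], coords[te_j][1])
    donor_scf.segments[te_j:te_j] = new_segments

    # delete one copy of each tract lineage from the receiver
    lost: list[str] = []
    tract_origins = [seg.origin for seg in tract]
    recv_by_origin: dict[int, int] = {}
    for i, seg in enumerate(receiver_scf.segments):
        if seg.origin not in recv_by_origin:
            recv_by_origin[seg.origin] = i
    to_delete = sorted(
        recv_by_origin[o] for o in set(tract_origins) if o in recv_by_origin
    )
    for i in reversed(to_delete):
        seg = receiver_scf.segments[i]
        if seg.gene is not None:
            lost.append(seg.gene.gene_id)
        del receiver_scf.segments[i]
    return tuple(gained), tuple(lost), donor_interval


def _candidate_te_pairs(scf: Scaffold, max_genes: int) -> list[tuple[int, int, int]]:
    """(te_i, te_j, hotspot) pairs of same-family TEs flanking 1..max_genes genes."""
    out = []
    te_idx = [i for i, s in enumerate(scf.segments) if s.kind == "te"]
    for pos, i in enumerate(te_idx):
        fam = scf.segments[i].family
        for j in te_idx[pos + 1 :]:
            n_genes = sum(
                1 for s in scf.segments[i + 1 : j] if s.kind == "gene"
            )
            if n_genes > max_genes:
                break
            if scf.segments[j].family == fam and n_genes >= 1:
                hs = scf.segments[i].hotspot if scf.segments[i].hotspot == scf.segments[j].hotspot else -1
                out.append((i, j, hs))
    return out


def apply_recurrent_nahr(
    hap1: Haplotype,
    hap2: Haplotype,
    config: SimConfig,
    rng: np.random.Generator,
    uid: _UidSource,
) -> list[NahrEvent]:
    """Apply ``n_nahr_events`` crossover events, biased into hotspots."""
    events: list[NahrEvent] = []
    for ev in range(config.n_nahr_events):
        donor_hap, recv_hap = (hap1, hap2) if rng.random() < 0.5 else (hap2, hap1)
        # pool candidates across scaffolds
        pool: list[tuple[int, int, int, int]] = []
        for k, scf in enumerate(donor_hap.scaffolds):
            for i, j, hs in _candidate_te_pairs(scf, config.tract_max_genes):
                pool.append((k, i, j, hs))
        if not pool:
            continue  # no eligible site pair; event skipped
        weights = np.array(
            [config.nahr_hotspot_bias if hs >= 0 else 1.0 for (_, _, _, hs) in pool]
        )
        weights /= weights.sum()
        k, i, j, hs = pool[int(rng.choice(len(pool), p=weights))]
        donor_scf = donor_hap.scaffolds[k]
        recv_scf = recv_hap.scaffolds[k]
        result = apply_unequal_crossover(donor_scf, recv_scf, i, j, uid)
        if result is None:
            continue
        gained, lost, interval = result
        events.append(
            NahrEvent(
                event_id=ev,
                scaffold_index=k,
                donor=donor_hap.name,
                receiver=recv_hap.name,
                family=donor_scf.segments[i].family or "",
                hotspot=hs,
                genes_gained=gained,
                genes_lost=lost,
                donor_interval=interval,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Stage 4: telomeres, gaps, truth coordinates
# ---------------------------------------------------------------------------

def _finalize_assembly(hap: Haplotype, config: SimConfig, rng: np.random.Generator, uid: _UidSource) -> None:
    """Add telomere arrays at both scaffold ends and N-gap runs."""
    n_gaps = config.gap_runs_hap1 if hap.name == "hap1" else config.gap_runs_hap2
    for scf in hap.scaffolds:
        tel5 = Segment("telomere", uid(), uid(), seq="CCCTAA" * config.telomere_copies)
        tel3 = Segment("telomere", uid(), uid(), seq=TELOMERE_MOTIF * config.telomere_copies)
        scf.segments.insert(0, tel5)
        scf.segments.append(tel3)
        inter = [i for i, s in enumerate(scf.segments) if s.kind == "intergenic" and s.length > 3 * config.gap_len]
        if not inter or n_gaps <= 0:
            continue
        for idx in sorted(rng.choice(inter, size=min(n_gaps, len(inter)), replace=False), reverse=True):
            host = scf.segments[idx]
            cut = len(host.seq) // 2
            parts = [
                Segment("intergenic", uid(), uid(), seq=host.seq[:cut], hotspot=host.hotspot, dup=host.dup),
                Segment("gap", uid(), uid(), seq="N" * config.gap_len, hotspot=host.hotspot, dup=host.dup),
                Segment("intergenic", uid(), uid(), seq=host.seq[cut:], hotspot=host.hotspot, dup=host.dup),
            ]
            scf.segments[idx : idx + 1] = parts


def _truth_tracts(haps: tuple[Haplotype, Haplotype], events: list[NahrEvent]) -> dict[str, list[Interval]]:
    """True disordered tracts at final coordinates.

    A hotspot that received at least one event contributes its full final
    span; duplicated segments outside hotspots contribute their contiguous
    runs.  Overlapping/adjacent intervals are merged per scaffold.
    """
    affected = {e.hotspot for e in events if e.hotspot >= 0}
    out: dict[str, list[Interval]] = {}
    for hap in haps:
        for scf in hap.scaffolds:
            coords = scf.coordinates()
            raw: list[tuple[int, int]] = []
            for seg, (s, e) in zip(scf.segments, coords):
                if (seg.hotspot in affected) or seg.dup:
                    raw.append((s, e))
            if not raw:
                out[scf.name] = []
                continue
            raw.sort()
            merged = [list(raw[0])]
            for s, e in raw[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[scf.name] = [Interval(scf.name, s, e, "truth") for s, e in merged]
    return out


# ---------------------------------------------------------------------------
# Stage 5: sequence divergence
# ---------------------------------------------------------------------------

def _pairwise_p_from_k(k: float) -> float:
    """Invert Jukes-Cantor: proportion of differing sites for distance k."""
    return 0.75 * (1.0 - np.exp(-4.0 * k / 3.0))


def _site_alternatives(codon: str) -> list[tuple[list[str], list[str]]]:
    """Per position: (synonymous alternatives, non-stop nonsynonymous ones)."""
    alts = []
    for pos in range(3):
        syn, nonsyn = [], []
        for nt in NT:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            (syn if CODON_TABLE[mutant] == CODON_TABLE[codon] else nonsyn).append(mutant)
        alts.append((syn, nonsyn))
    return alts


_ALT_CACHE: dict[str, list] = {}


def _mutate_cds(cds: str, q_syn: float, q_nonsyn: float, rng: np.random.Generator) -> str:
    """Codon-aware substitution: per site, a synonymous change with
    probability q_syn * (syn alternatives / 3) and a nonsynonymous one with
    q_nonsyn * (nonsyn alternatives / 3); start and stop codons are kept."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    u = rng.random(3 * len(codons))
    pick = rng.random(3 * len(codons))
    for ci in range(1, len(codons) - 1):  # preserve ATG and terminal stop
        codon = codons[ci]
        for pos in range(3):
            alts = _ALT_CACHE.get(codon)
            if alts is None:
                alts = _site_alternatives(codon)
                _ALT_CACHE[codon] = alts
            syn, nonsyn = alts[pos]
            p_s = q_syn * len(syn) / 3.0
            p_n = q_nonsyn * len(nonsyn) / 3.0
            r = u[3 * ci + pos]
            if r < p_s:
                codon = syn[int(pick[3 * ci + pos] * len(syn))]
            elif r < p_s + p_n:
                codon = nonsyn[int(pick[3 * ci + pos] * len(nonsyn))]
        codons[ci] = codon
    return "".join(codons)


def mutate_sequences(
    haps: tuple[Haplotype, Haplotype],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Diverge each haplotype from the ancestor at configured Ks/Ka targets.

    Rates are per branch (half the target pairwise distance); genes in
    duplicated or event-affected hotspot tracts use the elevated rates.
    """
    affected = {e.hotspot for e in truth.events if e.hotspot >= 0}
    q_syn_bg = _pairwise_p_from_k(config.background_ks) / 2.0
    q_non_bg = _pairwise_p_from_k(config.background_ka) / 2.0
    q_syn_dup = _pairwise_p_from_k(config.dup_ks) / 2.0
    q_non_dup = _pairwise_p_from_k(config.dup_ka) / 2.0
    for hap in haps:
        for scf in hap.scaffolds:
            for seg in scf.segments:
                if seg.gene is None:
                    continue
                elevated = seg.gene.dup or seg.dup or (seg.hotspot in affected)
                if elevated:
                    seg.gene.dup = True
                    truth.dup_genes.add(seg.gene.gene_id)
                    seg.gene.cds = _mutate_cds(seg.gene.cds, q_syn_dup, q_non_dup, rng)
                else:
                    seg.gene.cds = _mutate_cds(seg.gene.cds, q_syn_bg, q_non_bg, rng)


# ---------------------------------------------------------------------------
# Stage 6: expression
# ---------------------------------------------------------------------------

def simulate_expression(
    haps: tuple[Haplotype, Haplotype],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Stage profiles: conserved orthologs share an ancestral latent profile
    plus multiplicative noise; disordered-tract genes draw independent
    profiles (expected between-copy correlation ~ 0)."""
    latent: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    n = len(STAGES)
    for hap in haps:
        for scf in hap.scaffolds:
            for seg in scf.segments:
                if seg.gene is None:
                    continue
                g = seg.gene
                if g.gene_id in truth.dup_genes or g.dup:
                    prof = rng.lognormal(2.0, 1.0, n)
                else:
                    if g.ancestor_id not in latent:
                        latent[g.ancestor_id] = rng.lognormal(2.0, 1.0, n)
                    base = latent[g.ancestor_id]
                    noise = (
                        np.exp(rng.normal(0.0, config.expression_noise_sd, n))
                        if config.expression_noise_sd > 0
                        else 1.0
                    )
                    prof = base * noise
                profiles[g.gene_id] = prof
    return profiles


# ---------------------------------------------------------------------------
# Orchestration + emission
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> SimResult:
    """Run the full forward simulation deterministically from config.seed."""
    global _dup_counter
    _dup_counter = itertools.count(1)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    uid = _UidSource()
    ancestor = simulate_ancestor(config, rng, uid)
    hap1 = _copy_to_haplotype(ancestor, "hap1", config, uid)
    hap2 = _copy_to_haplotype(ancestor, "hap2", config, uid)
    insert_transposons(hap1, config, rng, uid)
    insert_transposons(hap2, config, rng, uid)
    events = apply_recurrent_nahr(hap1, hap2, config, rng, uid)
    _finalize_assembly(hap1, config, rng, uid)
    _finalize_assembly(hap2, config, rng, uid)
    tracts = _truth_tracts((hap1, hap2), events)
    ancestor_of = {}
    dup_genes: set[str] = set()
    for hap in (hap1, hap2):
        for scf in hap.scaffolds:
            for seg in scf.segments:
                if seg.gene is not None:
                    ancestor_of[seg.gene.gene_id] = seg.gene.ancestor_id
                    if seg.gene.dup:
                        dup_genes.add(seg.gene.gene_id)
    truth = SimTruth(events, tracts, ancestor_of, dup_genes)
    mutate_sequences((hap1, hap2), truth, config, rng)
    expression = simulate_expression((hap1, hap2), truth, config, rng)
    return SimResult(config, (hap1, hap2), truth, expression)


def _translate(cds: str) -> str:
    prot = []
    for i in range(0, len(cds) - 3 + 1, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            break
        prot.append(CODON_TABLE.get(codon, "X"))
    return "".join(prot)


def _hit_records(result: SimResult) -> list[HitRecord]:
    """Noise-free all-vs-all hit table from true homology: every pair of
    descendants of one ancestral gene, identity by columnwise comparison."""
    by_ancestor: dict[str, list[SimGene]] = {}
    for hap in result.haplotypes:
        for scf in hap.scaffolds:
            for seg in scf.segments:
                if seg.gene is not None:
                    by_ancestor.setdefault(seg.gene.ancestor_id, []).append(seg.gene)
    hits: list[HitRecord] = []
    for anc in sorted(by_ancestor):
        genes = sorted(by_ancestor[anc], key=lambda g: g.gene_id)
        for ga, gb in itertools.combinations(genes, 2):
            n = min(len(ga.cds), len(gb.cds))
            matches = sum(1 for x, y in zip(ga.cds, gb.cds) if x == y)
            ident = 100.0 * matches / n
            bit = max(50.0, 2.0 * matches / 3.0)
            for q, s in ((ga, gb), (gb, ga)):
                hits.append(
                    HitRecord(
                        q.gene_id, s.gene_id, round(ident, 2), n // 3,
                        (n - matches) // 3, 0, 1, n // 3, 1, n // 3,
                        1e-180, round(bit, 1),
                    )
                )
    return hits


def emit_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the complete dataset in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    species = result.config.species
    for hap in result.haplotypes:
        tag = hap.name
        genome, cds_recs, prot_recs, gff_lines, repeats = [], [], [], [], []
        gff_lines.append("##gff-version 3")
        for scf in hap.scaffolds:
            seqs = []
            pos = 0
            for seg in scf.segments:
                if seg.kind == "gene":
                    g = seg.gene
                    start1, end1 = pos + 1, pos + seg.length  # 1-based inclusive
                    gff_lines.append(
                        f"{scf.name}\tsim\tgene\t{start1}\t{end1}\t.\t+\t.\tID={g.gene_id}"
                    )
                    gff_lines.append(
                        f"{scf.name}\tsim\tmRNA\t{start1}\t{end1}\t.\t+\t.\t"
                        f"ID={g.gene_id}.t1;Parent={g.gene_id}"
                    )
                    gff_lines.append(
                        f"{scf.name}\tsim\tCDS\t{start1}\t{end1}\t.\t+\t0\t"
                        f"ID={g.gene_id}.t1.cds;Parent={g.gene_id}.t1"
                    )
                    cds_recs.append(SequenceRecord(f"{g.gene_id}.t1", g.cds))
                    prot_recs.append(SequenceRecord(f"{g.gene_id}.t1", _translate(g.cds), "protein"))
                    seqs.append(g.cds)
                else:
                    if seg.kind == "te":
                        repeats.append(
                            RepeatAnnotation(scf.name, pos, pos + seg.length,
                                             seg.family or "Unknown",
                                             TE_CLASSES.get(seg.family or "", "other"))
                        )
                    seqs.append(seg.seq)
                pos += seg.length
            genome.append(SequenceRecord(scf.name, "".join(seqs)))
        paths[f"{tag}_genome"] = outdir / f"{tag}.genome.fasta"
        io_formats.write_fasta(genome, paths[f"{tag}_genome"])
        paths[f"{tag}_gff"] = outdir / f"{tag}.genes.gff3"
        paths[f"{tag}_gff"].write_text("\n".join(gff_lines) + "\n")
        paths[f"{tag}_cds"] = outdir / f"{tag}.cds.fasta"
        io_formats.write_fasta(cds_recs, paths[f"{tag}_cds"])
        paths[f"{tag}_protein"] = outdir / f"{tag}.proteins.fasta"
        io_formats.write_fasta(prot_recs, paths[f"{tag}_protein"])
        paths[f"{tag}_repeats"] = outdir / f"{tag}.repeats.out"
        io_formats.write_repeatmasker_out(repeats, paths[f"{tag}_repeats"])
        # expression matrix
        import pandas as pd

        gene_ids = [
            seg.gene.gene_id
            for scf in hap.scaffolds
            for seg in scf.segments
            if seg.gene is not None
        ]
        mat = pd.DataFrame(
            [result.expression[g] for g in gene_ids], index=gene_ids, columns=list(STAGES)
        )
        paths[f"{tag}_expression"] = outdir / f"{tag}.expression.tsv"
        io_formats.write_expression_tsv(mat, paths[f"{tag}_expression"])

    paths["hits"] = outdir / "hits.tsv"
    io_formats.write_tabular_hits(_hit_records(result), paths["hits"])

    # orthogroups: one group per ancestral lineage
    from .duplication import OrthoGroup, write_orthogroups

    by_anc: dict[str, list[str]] = {}
    for gid, anc in result.truth.ancestor_of.items():
        by_anc.setdefault(anc, []).append(gid)
    groups = [
        OrthoGroup(f"OG_{anc}", tuple(sorted(members)))
        for anc, members in sorted(by_anc.items())
    ]
    paths["orthogroups"] = outdir / "orthogroups.txt"
    write_orthogroups(groups, {g: species for g in result.truth.ancestor_of}, paths["orthogroups"])

    truth_ivs = [iv for ivs in result.truth.nsr_tracts.values() for iv in ivs]
    paths["truth_bed"] = outdir / "truth_nsr.bed"
    io_formats.write_bed(truth_ivs, paths["truth_bed"])

    paths["events"] = outdir / "events.tsv"
    with open(paths["events"], "w") as fh:
        fh.write("event_id\tscaffold_index\tdonor\treceiver\tfamily\thotspot\t"
                 "genes_gained\tgenes_lost\tdonor_start\tdonor_end\n")
        for e in result.truth.events:
            fh.write(
                f"{e.event_id}\t{e.scaffold_index}\t{e.donor}\t{e.receiver}\t{e.family}\t"
                f"{e.hotspot}\t{','.join(e.genes_gained)}\t{','.join(e.genes_lost)}\t"
                f"{e.donor_interval[0]}\t{e.donor_interval[1]}\n"
            )
    return paths
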