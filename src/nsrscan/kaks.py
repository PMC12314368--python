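"""Protein-guided codon alignment and Nei-Gojobori (1986) Ka/Ks estimation.

Site counting treats each codon position as contributing a synonymous-site
fraction equal to (number of synonymous single-nucleotide alternatives)/3;
changes that would create a stop codon count toward the nonsynonymous
fraction, so S + N = 3 x n_codons holds exactly.  Observed differences in
codons differing at more than one position are averaged over all minimal
mutational pathways; pathways passing through a stop codon are excluded
unless every pathway does.  Proportions are corrected with the Jukes-Cantor
formula K = -(3/4) ln(1 - (4/3) p); p >= 3/4 is flagged as saturated rather
than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

NT = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

CODON_TABLE: dict[str, str] = {
    a + b + c: str(Seq(a + b + c).translate())
    for a in NT
    for b in NT
    for c in NT
}
SENSE_CODONS = tuple(c for c in CODON_TABLE if c not in STOP_CODONS)


class SaturationWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# Protein alignment
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_PROT_ALPHABET = set(str(_BLOSUM62.alphabet))


def global_protein_align(
    prot_a: str,
    prot_b: str,
    substitution_table=_BLOSUM62,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[str, str]:
    """Optimal global alignment of two protein sequences under affine gaps.

    Returns the two gapped strings.  The traceback is deterministic (the
    first optimal alignment in the aligner's canonical order).
    """
    if not prot_a or not prot_b:
        raise ValueError("empty protein sequence")
    alphabet = set(str(substitution_table.alphabet))
    for name, p in (("A", prot_a), ("B", prot_b)):
        bad = set(p) - alphabet
        if bad:
            raise ValueError(f"protein {name}: invalid residues {sorted(bad)}")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_table
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(prot_a, prot_b)[0]
    return str(aln[0]), str(aln[1])


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class CodonAlignment:
    """Gap-free aligned codon columns retained for substitution counting."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon sequences differ in length")
        for pair in zip(self.codons_a, self.codons_b):
            for codon in pair:
                if codon not in CODON_TABLE or codon in STOP_CODONS:
                    raise ValueError(f"invalid or stop codon {codon!r} in alignment")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


def codon_align_from_protein(
    aln_a: str, aln_b: str, cds_a: str, cds_b: str
) -> CodonAlignment:
    """Expand a gapped protein alignment to codons and keep countable columns.

    Columns containing a gap, an ambiguous base, or a stop codon are dropped.
    The CDS must translate to the ungapped protein (terminal stop optional).
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for col, (ra, rb) in enumerate(zip(aln_a, aln_b)):
        codon_a = codon_b = None
        if ra != "-":
            codon_a = cds_a[3 * ia : 3 * ia + 3]
            if len(codon_a) != 3:
                raise ValueError(f"CDS A shorter than protein alignment at codon {ia}")
            if codon_a in CODON_TABLE and CODON_TABLE[codon_a] != ra and ra != "X":
                raise ValueError(
                    f"CDS A codon {ia} ({codon_a}) translates to "
                    f"{CODON_TABLE[codon_a]}, alignment has {ra}"
                )
            ia += 1
        if rb != "-":
            codon_b = cds_b[3 * ib : 3 * ib + 3]
            if len(codon_b) != 3:
                raise ValueError(f"CDS B shorter than protein alignment at codon {ib}")
            if codon_b in CODON_TABLE and CODON_TABLE[codon_b] != rb and rb != "X":
                raise ValueError(
                    f"CDS B codon {ib} ({codon_b}) translates to "
                    f"{CODON_TABLE[codon_b]}, alignment has {rb}"
                )
            ib += 1
        if codon_a is None or codon_b is None:
            continue
        if codon_a not in CODON_TABLE or codon_b not in CODON_TABLE:
            continue  # ambiguous bases
        if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
            continue
        pairs.append((codon_a, codon_b))
    remaining_a = cds_a[3 * ia :]
    remaining_b = cds_b[3 * ib :]
    for name, rem, idx in (("A", remaining_a, ia), ("B", remaining_b, ib)):
        if rem and rem not in STOP_CODONS:
            raise ValueError(f"CDS {name} has unexpected trailing codon at index {idx}")
    return CodonAlignment(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; sums to 3."""
    syn = 0.0
    for pos in range(3):
        for alt in NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TABLE[mutant] == CODON_TABLE[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences for one pair.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are discarded when any stop-free pathway exists.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[int, int, bool]] = []  # (syn steps, nonsyn steps, clean)
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        clean = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                clean = False
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        pathways.append((syn, nonsyn, clean))
    usable = [p for p in pathways if p[2]] or pathways
    sd = sum(p[0] for p in usable) / len(usable)
    nd = sum(p[1] for p in usable) / len(usable)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None when saturated (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion below 0")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


@dataclass(frozen=True, slots=True)
class KaKsResult:
    S: float
    N: float
    sd: float
    nd: float
    ps: float
    pn: float
    Ka: float | None  # None = saturated
    Ks: float | None
    ratio: float | None  # Ka/Ks; None when undefined

    @property
    def saturated(self) -> bool:
        return self.Ka is None or self.Ks is None


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks from a gap-free codon alignment."""
    if alignment.n_codons < 1:
        raise ValueError("alignment must contain at least one codon")
    S = N = sd = nd = 0.0
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        d_s, d_n = codon_pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    if Ka is None or Ks is None or Ks == 0.0:
        ratio = None
    else:
        ratio = Ka / Ks
    return KaKsResult(S, N, sd, nd, ps, pn, Ka, Ks, ratio)


def kaks_from_cds(cds_a: str, cds_b: str, **align_kwargs) -> KaKsResult:
    """Convenience wrapper: translate, align proteins, codon-align, run NG86."""
    prot_a = _translate_cds(cds_a, "A")
    prot_b = _translate_cds(cds_b, "B")
    aln_a, aln_b = global_protein_align(prot_a, prot_b, **align_kwargs)
    codon_aln = codon_align_from_protein(aln_a, aln_b, cds_a, cds_b)
    return ng86(codon_aln)


def _translate_cds(cds: str, label: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS {label}: length not a multiple of 3")
    residues = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            if i == len(cds) - 3:
                break  # terminal stop
            raise ValueError(f"CDS {label}: internal stop at codon {i // 3}")
        if codon not in CODON_TABLE:
            residues.append("X")
        else:
            residues.append(CODON_TABLE[codon])
    if not residues:
        raise ValueError(f"CDS {label}: no codons")
    return "".join(residues)


# ---------------------------------------------------------------------------
# Homolog classification
# ---------------------------------------------------------------------------

METRICS = ("ks", "ka", "ka_over_ks")


@dataclass(frozen=True, slots=True)
class HomologPair:
    gene_a: str
    gene_b: str
    kaks: KaKsResult
    is_homologous: bool


def classify_homologous(
    result: KaKsResult, threshold: float = 0.3, metric: str = "ks"
) -> bool:
    """True iff the chosen divergence metric is strictly below the threshold.

    A saturated or undefined metric always classifies as non-homologous.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose one of {METRICS}")
    value = {"ks": result.Ks, "ka": result.Ka, "ka_over_ks": result.ratio}[metric]
    if value is None:
        return False
    return value < threshold
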