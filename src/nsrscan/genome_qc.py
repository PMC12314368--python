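"""Telomere-array detection, gap counting, and Ref/Alt haplotype assignment.

A haplotype pair is resolved to reference (Ref) and alternate (Alt) using
three ordered rules: (i) the scaffold that alone carries telomere arrays at
both ends is Ref; (ii) if both do, the one with fewer assembly gaps is Ref;
(iii) otherwise the one with fewer gaps is Ref.  Exact ties fall back to the
longer scaffold (documented tie-break).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import NUCLEOTIDES, SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class TelomereArray:
    scaffold_id: str
    start: int
    end: int
    motif_copies: int
    scaffold_end: str  # {5prime, 3prime, internal}
    strand: str = "+"


@dataclass(frozen=True, slots=True)
class GapRun:
    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class ScaffoldInfo:
    """Per-scaffold summary consumed by the Ref/Alt assignment."""

    scaffold_id: str
    length: int
    telomere_5prime: bool
    telomere_3prime: bool
    n_gaps: int

    @property
    def both_ends(self) -> bool:
        return self.telomere_5prime and self.telomere_3prime


@dataclass(frozen=True, slots=True)
class HaplotypeAssignment:
    ref_id: str
    alt_id: str
    rule_used: str  # {i, ii, iii, tiebreak}

    def __post_init__(self) -> None:
        if self.ref_id == self.alt_id:
            raise ValueError("ref and alt scaffolds must differ")


def _check_nucleotide(seq: SequenceRecord) -> str:
    residues = seq.residues.upper()
    bad = set(residues) - NUCLEOTIDES
    if bad:
        raise ValueError(f"{seq.seq_id}: non-nucleotide characters {sorted(bad)}")
    return residues


def _motif_runs(residues: str, motif: str, min_copies: int, max_mismatch_frac: float):
    """Maximal tandem runs of `motif`, tolerating in-phase degenerate copies.

    Exact matches are clustered left to right; a gap between consecutive
    exact copies is bridged when it is a whole number of motif lengths
    (substitution-degenerate copies keep phase) and the running mismatch
    fraction stays within bounds.
    """
    m = len(motif)
    starts = [match.start() for match in re.finditer(f"(?={re.escape(motif)})", residues)]
    runs: list[tuple[int, int, int]] = []  # (start, end, copies)
    i = 0
    while i < len(starts):
        run_start = starts[i]
        cur_end = run_start + m
        exact = 1
        degenerate = 0
        j = i + 1
        while j < len(starts):
            nxt = starts[j]
            if nxt < cur_end:  # overlapping self-match inside the run
                j += 1
                continue
            gap = nxt - cur_end
            if gap == 0:
                exact += 1
                cur_end = nxt + m
                j += 1
                continue
            if gap % m == 0:
                bridged = gap // m
                total = exact + degenerate + bridged + 1
                if (degenerate + bridged) / total <= max_mismatch_frac:
                    degenerate += bridged
                    exact += 1
                    cur_end = nxt + m
                    j += 1
                    continue
            break
        copies = exact + degenerate
        if copies >= min_copies:
            runs.append((run_start, cur_end, copies))
        i = j
    return runs


def find_telomere_arrays(
    seq: SequenceRecord,
    motif: str = "TTAGGG",
    min_copies: int = 25,
    max_mismatch_frac: float = 0.1,
    end_window: int = 10_000,
) -> list[TelomereArray]:
    """Detect tandem telomere-motif arrays on both strands.

    The forward motif is reported on ``+`` and its reverse complement
    (``CCCTAA`` for the metazoan motif) on ``-``.  Arrays whose edge lies
    within ``end_window`` of a scaffold end are labelled 5prime/3prime.
    """
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    residues = _check_nucleotide(seq)
    n = len(residues)
    arrays: list[TelomereArray] = []
    for strand, mot in (("+", motif.upper()), ("-", revcomp(motif.upper()))):
        if strand == "-" and mot == motif.upper():
            continue  # palindromic motif: avoid double-reporting
        for start, end, copies in _motif_runs(residues, mot, min_copies, max_mismatch_frac):
            if start < end_window:
                label = "5prime"
            elif n - end < end_window:
                label = "3prime"
            else:
                label = "internal"
            arrays.append(TelomereArray(seq.seq_id, start, end, copies, label, strand))
    arrays.sort(key=lambda a: a.start)
    return arrays


def count_gap_runs(seq: SequenceRecord, min_gap_len: int = 10) -> list[GapRun]:
    """Maximal runs of N of length >= min_gap_len."""
    residues = _check_nucleotide(seq)
    return [
        GapRun(seq.seq_id, m.start(), m.end())
        for m in re.finditer(f"N{{{min_gap_len},}}", residues)
    ]


def scaffold_info(
    seq: SequenceRecord,
    motif: str = "TTAGGG",
    min_copies: int = 25,
    max_mismatch_frac: float = 0.1,
    end_window: int = 10_000,
    min_gap_len: int = 10,
) -> ScaffoldInfo:
    arrays = find_telomere_arrays(seq, motif, min_copies, max_mismatch_frac, end_window)
    gaps = count_gap_runs(seq, min_gap_len)
    return ScaffoldInfo(
        scaffold_id=seq.seq_id,
        length=len(seq),
        telomere_5prime=any(a.scaffold_end == "5prime" for a in arrays),
        telomere_3prime=any(a.scaffold_end == "3prime" for a in arrays),
        n_gaps=len(gaps),
    )


def assign_ref_alt(info_a: ScaffoldInfo, info_b: ScaffoldInfo) -> HaplotypeAssignment:
    """Resolve a homologous scaffold pair to Ref/Alt (rules i-iii + tie-break)."""
    for f in ("scaffold_id", "length", "telomere_5prime", "telomere_3prime", "n_gaps"):
        if getattr(info_a, f, None) is None or getattr(info_b, f, None) is None:
            raise ValueError(f"missing scaffold info field {f!r}")

    a_both, b_both = info_a.both_ends, info_b.both_ends
    if a_both != b_both:
        ref, alt = (info_a, info_b) if a_both else (info_b, info_a)
        return HaplotypeAssignment(ref.scaffold_id, alt.scaffold_id, "i")
    if info_a.n_gaps != info_b.n_gaps:
        ref, alt = (info_a, info_b) if info_a.n_gaps < info_b.n_gaps else (info_b, info_a)
        return HaplotypeAssignment(ref.scaffold_id, alt.scaffold_id, "ii" if a_both else "iii")
    # exact tie on telomere status and gap count: longer scaffold is Ref;
    # equal lengths fall back to lexicographic id so the choice is symmetric
    key_a = (-info_a.length, info_a.scaffold_id)
    key_b = (-info_b.length, info_b.scaffold_id)
    if key_a <= key_b:
        return HaplotypeAssignment(info_a.scaffold_id, info_b.scaffold_id, "tiebreak")
    return HaplotypeAssignment(info_b.scaffold_id, info_a.scaffold_id, "tiebreak")
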