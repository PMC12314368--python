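"""Core record types shared across the toolkit.

All genomic coordinates are 0-based half-open.  Conversion from 1-based
inclusive conventions (GFF3, RepeatMasker) happens at file boundaries only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX*")
PFAM_RE = re.compile(r"^PF\d{5}$")

REPEAT_CLASSES = ("LTR", "LINE", "SINE", "DNA", "other")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """One annotated gene: the ordered unit of all synteny logic."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    species: str = ""
    haplotype: str = "unassigned"
    cds_id: str | None = None
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    seq_id: str
    residues: str
    moltype: str = "nucleotide"  # or "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id}: empty")
        alphabet = NUCLEOTIDES if self.moltype == "nucleotide" else AMINO_ACIDS
        bad = set(self.residues.upper()) - alphabet
        if bad:
            raise ValueError(
                f"sequence {self.seq_id}: residues {sorted(bad)} not allowed for {self.moltype}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, slots=True)
class HitRecord:
    """One row of a 12-column tabular similarity search."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: e_value < 0")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: pct_identity outside [0, 100]"
            )


@dataclass(frozen=True, slots=True)
class DomainAnnotation:
    gene_id: str
    domain_acc: str
    description: str
    start: int  # protein coordinates, 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if not PFAM_RE.match(self.domain_acc):
            raise ValueError(f"domain accession {self.domain_acc!r} does not match PF#####")
        if not self.start < self.end:
            raise ValueError(f"domain {self.domain_acc} on {self.gene_id}: start >= end")


@dataclass(frozen=True, slots=True)
class RepeatAnnotation:
    scaffold_id: str
    start: int
    end: int
    family: str
    repeat_class: str = "other"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"repeat {self.family} on {self.scaffold_id}: start >= end")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {self.repeat_class!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class Interval:
    """A plain genomic interval, used for BED round-trips."""

    scaffold_id: str
    start: int
    end: int
    name: str = ""
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}")
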