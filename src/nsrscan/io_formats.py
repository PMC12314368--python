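"""Readers and writers for the standard formats the pipeline touches.

Every reader normalises to the internal coordinate convention (0-based,
half-open); every writer converts back where a format demands 1-based
inclusive coordinates.
"""

from __future__ import annotations

import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    DomainAnnotation,
    GeneModel,
    HitRecord,
    Interval,
    RepeatAnnotation,
    SequenceRecord,
)


class ParseError(ValueError):
    """Raised when an input file violates its declared dialect."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF3_COLUMNS = 9


def _prescan_gff3(path: str | Path) -> None:
    """Validate line structure before handing the file to gffutils,
    so errors can name the offending line."""
    seen_gene_ids: set[str] = set()
    in_fasta = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                in_fasta = True
            if in_fasta or not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF3_COLUMNS:
                raise ParseError(
                    f"{path}: line {lineno}: expected {_GFF3_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(
                    f"{path}: line {lineno}: invalid 1-based interval {start}..{end}"
                )
            if fields[2] == "gene":
                m = re.search(r"(?:^|;)ID=([^;]+)", fields[8])
                if m:
                    gid = m.group(1)
                    if gid in seen_gene_ids:
                        raise ParseError(f"{path}: line {lineno}: duplicate gene ID {gid!r}")
                    seen_gene_ids.add(gid)


def read_gff3(
    path: str | Path,
    species: str = "",
    haplotype: str = "unassigned",
) -> list[GeneModel]:
    """Load gene features from a GFF3 file.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    For multi-isoform genes, the mRNA with the longest total CDS is kept as
    the single representative (ties broken by transcript ID).  Genes are
    returned sorted by (scaffold_id, start, gene_id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_gff3(path)
    if not any(
        line.strip() and not line.startswith("#") for line in path.read_text().splitlines()
    ):
        return []
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - prescan catches most issues
        raise ParseError(f"{path}: GFF3 parse failure: {exc}") from exc

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best_mrna_id: str | None = None
        best_cds_len = -1
        for mrna in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS")
            )
            if cds_len > best_cds_len or (
                cds_len == best_cds_len and (best_mrna_id is None or mrna.id < best_mrna_id)
            ):
                best_cds_len = cds_len
                best_mrna_id = mrna.id
        genes.append(
            GeneModel(
                gene_id=gene.id,
                scaffold_id=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                species=species,
                haplotype=haplotype,
                cds_id=best_mrna_id,
                protein_id=best_mrna_id,
            )
        )
    genes.sort(key=lambda g: (g.scaffold_id, g.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, moltype: str = "nucleotide") -> dict[str, SequenceRecord]:
    """Read a FASTA file into SequenceRecords keyed by sequence id."""
    records: dict[str, SequenceRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = SequenceRecord(rec.id, str(rec.seq).upper(), moltype=moltype)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular similarity hits (12-column, outfmt-6 style)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
]


def read_tabular_hits(path: str | Path, max_hits_per_query: int = 5) -> list[HitRecord]:
    """Read 12-column tabular hits; drop self-hits; keep the best
    ``max_hits_per_query`` subjects per query by bit score (ties broken by
    lexicographic subject id)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(_HIT_COLUMNS):
        raise ParseError(
            f"{path}: expected {len(_HIT_COLUMNS)} columns, found {df.shape[1]}"
        )
    df.columns = _HIT_COLUMNS
    for col in ("pct_identity", "e_value", "bit_score"):
        df[col] = df[col].astype(float)
    for col in ("aln_length", "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end"):
        df[col] = df[col].astype(int)
    df = df[df.query_id != df.subject_id]
    df = df.sort_values(
        ["query_id", "bit_score", "subject_id"], ascending=[True, False, True]
    )
    df = df.groupby("query_id", sort=False).head(max_hits_per_query)
    return [HitRecord(**row) for row in df.to_dict("records")]


def write_tabular_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t"
                f"{h.s_end}\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


# ---------------------------------------------------------------------------
# InterProScan TSV
# ---------------------------------------------------------------------------

def read_interproscan_tsv(path: str | Path, pfam_only: bool = True) -> list[DomainAnnotation]:
    """Read an InterProScan TSV (>= 11 columns).  By default only Pfam rows
    (accessions matching PF#####) are returned.  Protein coordinates are
    converted to 0-based half-open."""
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 8 InterProScan columns"
                )
            gene_id, acc, desc = fields[0], fields[4], fields[5]
            if pfam_only and not re.match(r"^PF\d{5}$", acc):
                continue
            try:
                start, end = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad domain coordinates") from exc
            out.append(DomainAnnotation(gene_id, acc, desc, start - 1, end))
    return out


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_CLASS_MAP = {"LTR": "LTR", "LINE": "LINE", "SINE": "SINE", "DNA": "DNA"}


def _repeat_class_of(class_family: str) -> tuple[str, str]:
    """Split a RepeatMasker class/family string like ``LTR/Copia``."""
    if "/" in class_family:
        cls, fam = class_family.split("/", 1)
    else:
        cls, fam = class_family, class_family
    for key, norm in _RM_CLASS_MAP.items():
        if cls.upper().startswith(key):
            return norm, fam
    return "other", fam


def read_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Read a RepeatMasker ``.out`` file (whitespace-separated, 3 header
    lines).  Coordinates converted from 1-based inclusive."""
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score", "There were no")):
                continue  # header / empty-result banner
            fields = stripped.split()
            if len(fields) < 11:
                raise ParseError(
                    f"{path}: line {lineno}: not a RepeatMasker .out row: {stripped!r}"
                )
            try:
                scaffold = fields[4]
                start, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad coordinates") from exc
            cls, fam = _repeat_class_of(fields[10])
            # column 9 is the repeat name; prefer the family part of class/family
            if fam == fields[10] and "/" not in fields[10]:
                fam = fields[9]
            out.append(RepeatAnnotation(scaffold, start - 1, end, fam, cls))
    return out


def write_repeatmasker_out(repeats: Iterable[RepeatAnnotation], path: str | Path) -> None:
    """Write a minimal RepeatMasker-style .out table (for simulated data)."""
    header = (
        "   SW  perc perc perc  query     position in query    matching repeat"
        "       position in repeat\n"
        "score  div. del. ins.  sequence  begin end (left)     repeat class/family"
        "  begin end (left) ID\n\n"
    )
    class_prefix = {"LTR": "LTR", "LINE": "LINE", "SINE": "SINE", "DNA": "DNA", "other": "Unknown"}
    with open(path, "w") as fh:
        fh.write(header)
        for i, r in enumerate(repeats, start=1):
            cf = f"{class_prefix[r.repeat_class]}/{r.family}"
            fh.write(
                f"  250  1.0  0.0  0.0  {r.scaffold_id}  {r.start + 1}  {r.end}  (0)  +  "
                f"{r.family}  {cf}  1  {r.end - r.start}  (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-stages TSV matrix.  Values must be non-negative and
    gene ids unique."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dupes[:5]}")
    if (df.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative expression values present")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write BED3+ (0-based half-open), sorted by (scaffold, start, end).

    Name/score/strand columns are emitted only when at least one interval
    carries them, so BED3 inputs round-trip byte-identically.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.scaffold_id, iv.start, iv.end))
    n_extra = 0
    if any(iv.strand is not None for iv in ivs):
        n_extra = 3
    elif any(iv.score is not None for iv in ivs):
        n_extra = 2
    elif any(iv.name for iv in ivs):
        n_extra = 1
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.scaffold_id, str(iv.start), str(iv.end)]
            if n_extra >= 1:
                cols.append(iv.name or ".")
            if n_extra >= 2:
                cols.append("0" if iv.score is None else f"{iv.score:g}")
            if n_extra >= 3:
                cols.append(iv.strand or ".")
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad BED coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            score = float(fields[4]) if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 and fields[5] != "." else None
            out.append(Interval(fields[0], start, end, name, score, strand))
    return out


# ---------------------------------------------------------------------------
# MCScanX .collinearity import
# ---------------------------------------------------------------------------

_MCSX_HEADER = re.compile(
    r"^##\s*Alignment\s+(?P<num>\d+):\s*score=(?P<score>[\d.eE+-]+)\s+"
    r"e_value=(?P<evalue>[\d.eE+-]+)\s+N=(?P<n>\d+)\s+"
    r"(?P<sa>\S+?)&(?P<sb>\S+)\s+(?P<orient>plus|minus)"
)


def read_mcscanx_collinearity(path: str | Path):
    """Import blocks from native MCScanX ``.collinearity`` output.

    Returns a list of :class:`~nsrscan.collinearity.CollinearBlock`; anchor
    rank indices are filled with the within-block ordinal (the native file
    does not carry gene ranks).
    """
    from .collinearity import AnchorPair, CollinearBlock

    blocks: list[CollinearBlock] = []
    current: dict | None = None
    anchors: list[AnchorPair] = []

    def _flush():
        nonlocal current, anchors
        if current is not None:
            idx_b = (
                range(len(anchors))
                if current["orient"] == "plus"
                else range(len(anchors) - 1, -1, -1)
            )
            pairs = [
                AnchorPair(i, j, a.gene_a, a.gene_b, a.hit_evalue)
                for i, (j, a) in enumerate(zip(idx_b, anchors))
            ]
            blocks.append(
                CollinearBlock(
                    anchors=tuple(pairs),
                    orientation="parallel" if current["orient"] == "plus" else "antiparallel",
                    score=current["score"],
                    e_value=current["evalue"],
                    scaffold_a=current["sa"],
                    scaffold_b=current["sb"],
                    validate=False,
                )
            )
        current, anchors = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            m = _MCSX_HEADER.match(line)
            if m:
                _flush()
                current = {
                    "score": float(m.group("score")),
                    "evalue": float(m.group("evalue")),
                    "sa": m.group("sa"),
                    "sb": m.group("sb"),
                    "orient": m.group("orient"),
                }
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3 or current is None:
                raise ParseError(
                    f"{path}: line {lineno}: not a .collinearity anchor row: {line!r}"
                )
            from .collinearity import AnchorPair as _AP

            evalue = float(fields[3]) if len(fields) > 3 else 0.0
            anchors.append(_AP(0, 0, fields[1], fields[2], evalue))
    _flush()
    return blocks


def write_mcscanx_collinearity(blocks, path: str | Path) -> None:
    """Export blocks in MCScanX-compatible ``.collinearity`` text."""
    with open(path, "w") as fh:
        fh.write("############### Collinearity output ###############\n")
        for i, b in enumerate(blocks):
            orient = "plus" if b.orientation == "parallel" else "minus"
            fh.write(
                f"## Alignment {i}: score={b.score:g} e_value={b.e_value:.3g} "
                f"N={len(b.anchors)} {b.scaffold_a}&{b.scaffold_b} {orient}\n"
            )
            for j, a in enumerate(b.anchors):
                fh.write(f"{i:3d}-{j:3d}:\t{a.gene_a}\t{a.gene_b}\t{a.hit_evalue:.3g}\n")
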