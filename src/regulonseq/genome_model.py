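"""Genome annotation model, coordinate conventions, and format I/O.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open (``Interval``).  Gene models
keep the 1-based, inclusive coordinates of GFF3 so that reading and writing
a GFF3 file is lossless; BED output is 0-based half-open.  The conversion
happens only at the I/O boundary, never inside the analysis code.

A :class:`GenomeAnnotation` is a single replicon (linear by default, circular
behind a flag that only affects the terminal intergenic interval) with genes
sorted by start.  Overlapping genes are permitted; any base covered by at
least one gene counts as intragenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_KINDS = ("protein_coding", "rRNA", "tRNA")

#: GFF3 feature type used for each gene kind (and its inverse for parsing).
_KIND_TO_GFF = {"protein_coding": "gene", "rRNA": "rRNA", "tRNA": "tRNA"}
_GFF_TO_KIND = {"gene": "protein_coding", "CDS": "protein_coding",
                "rRNA": "rRNA", "tRNA": "tRNA"}


class GFFParseError(ValueError):
    """Raised for a malformed GFF3 line; message names the line number."""


@dataclass(frozen=True)
class Interval:
    """A 0-based, half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Gene:
    """A gene locus in 1-based inclusive coordinates, as in GFF3."""

    locus_id: str
    start: int
    end: int
    strand: str
    kind: str = "protein_coding"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.locus_id}: invalid span {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_id}: strand must be + or -")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"{self.locus_id}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> Interval:
        """The gene body as a 0-based half-open interval."""
        return Interval(self.start - 1, self.end)

    @property
    def start_codon_pos(self) -> int:
        """0-based position of the first base of the start codon."""
        return self.start - 1 if self.strand == "+" else self.end - 1


@dataclass
class GenomeAnnotation:
    """One replicon: ordered gene models plus an optional sequence."""

    genome_length: int
    genes: list[Gene] = field(default_factory=list)
    sequence: str | None = None
    seqid: str = "chr1"
    circular: bool = False

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        seen: set[str] = set()
        for g in self.genes:
            if g.end > self.genome_length:
                raise ValueError(
                    f"{g.locus_id} extends past genome length "
                    f"{self.genome_length}")
            if g.locus_id in seen:
                raise ValueError(f"duplicate locus_id {g.locus_id}")
            seen.add(g.locus_id)
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise ValueError("sequence length does not match genome_length")

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def gene(self, locus_id: str) -> Gene:
        for g in self.genes:
            if g.locus_id == locus_id:
                return g
        raise KeyError(locus_id)


# ---------------------------------------------------------------------------
# Intergenic geometry
# ---------------------------------------------------------------------------

def gene_cover(ann: GenomeAnnotation) -> list[Interval]:
    """Merged union of all gene bodies, as disjoint sorted intervals."""
    merged: list[list[int]] = []
    for g in ann.genes:
        s, e = g.start - 1, g.end
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [Interval(s, e) for s, e in merged]


def intergenic_regions(ann: GenomeAnnotation) -> list[Interval]:
    """Maximal intervals covered by no gene.

    Together with the gene-covered union these partition the replicon; on a
    circular replicon the wrap-around gap is still reported as (up to) two
    linear intervals so downstream interval arithmetic stays simple.
    """
    out: list[Interval] = []
    pos = 0
    for iv in gene_cover(ann):
        if iv.start > pos:
            out.append(Interval(pos, iv.start))
        pos = max(pos, iv.end)
    if pos < ann.genome_length:
        out.append(Interval(pos, ann.genome_length))
    return out


def intergenic_fraction(ann: GenomeAnnotation) -> float:
    """Fraction of replicon bases inside no gene (1 − intragenic fraction)."""
    inter = sum(len(iv) for iv in intergenic_regions(ann))
    return inter / ann.genome_length


def is_intergenic(ann: GenomeAnnotation, pos: int) -> bool:
    """Whether 0-based position ``pos`` falls outside every gene body."""
    for g in ann.genes:
        if g.start - 1 <= pos < g.end:
            return False
        if g.start - 1 > pos:
            break
    return True


# ---------------------------------------------------------------------------
# GFF3 / FASTA / BED I/O
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> GenomeAnnotation:
    """Read gene/CDS/rRNA/tRNA features from a GFF3 file.

    The ``##sequence-region`` pragma supplies the replicon length; without it
    the length defaults to the rightmost feature end.  ``locus_tag`` (or
    failing that ``ID``) becomes the locus id; a duplicate locus id is an
    error.  Malformed lines raise :class:`GFFParseError` naming the line.
    """
    genes: list[Gene] = []
    genome_length = 0
    seqid = "chr1"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        seqid = parts[1]
                        genome_length = int(parts[3])
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}")
            sid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in _GFF_TO_KIND:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GFFParseError(
                    f"line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise GFFParseError(f"line {lineno}: bad strand {strand!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            locus = attr.get("locus_tag") or attr.get("ID")
            if not locus:
                raise GFFParseError(
                    f"line {lineno}: feature without locus_tag or ID")
            seqid = sid
            genes.append(Gene(locus, start_i, end_i, strand,
                              kind=_GFF_TO_KIND[ftype],
                              name=attr.get("Name")))
    if not genome_length:
        genome_length = max((g.end for g in genes), default=0)
    try:
        return GenomeAnnotation(genome_length, genes, seqid=seqid)
    except ValueError as exc:  # duplicate locus ids etc.
        raise GFFParseError(str(exc)) from exc


def write_gff(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3 (inverse of :func:`read_gff`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.seqid} 1 {ann.genome_length}\n")
        for g in ann.genes:
            attrs = f"ID={g.locus_id};locus_tag={g.locus_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write("\t".join([
                ann.seqid, "regulonseq", _KIND_TO_GFF[g.kind],
                str(g.start), str(g.end), ".", g.strand, ".", attrs]) + "\n")


def read_fasta(path: str | Path) -> str:
    """Read the (single) genome sequence from a FASTA file, uppercased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(sequence: str, path: str | Path, seqid: str = "chr1") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=seqid, description="")],
                str(path), "fasta")


def write_bed(intervals: Iterable[Interval], path: str | Path,
              seqid: str = "chr1", name_prefix: str = "region") -> None:
    """Write intervals as BED6 (0-based half-open, strand '.')."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals, start=1):
            fh.write(f"{seqid}\t{iv.start}\t{iv.end}\t{name_prefix}_{i}"
                     f"\t0\t.\n")


def with_sequence(ann: GenomeAnnotation, sequence: str) -> GenomeAnnotation:
    """Return a copy of ``ann`` carrying ``sequence``."""
    return GenomeAnnotation(ann.genome_length, list(ann.genes),
                            sequence=sequence, seqid=ann.seqid,
                            circular=ann.circular)
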