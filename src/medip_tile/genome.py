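"""Genome containers and flat-file IO.

Sequences follow the soft-masking convention: lowercase bases are
repeat-masked, ``N`` is unknown. All internal coordinates are 0-based
half-open; GFF3 output is converted to 1-based inclusive on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Gene:
    """A gene model reduced to what promoter extraction needs.

    ``tss`` is the 0-based position of the transcript's 5' base; for a
    minus-strand gene this is the *rightmost* transcribed base.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int
    start: int  # gene span, 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start <= self.tss < self.end:
            raise ValueError(f"TSS {self.tss} outside gene span [{self.start}, {self.end})")


@dataclass
class GenomeAnnotation:
    """Chromosome sequences plus gene records."""

    sequences: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.sequences:
                raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (gene + mRNA features, one transcript per gene)

_GFF_SOURCE = "medip_tile"


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for name, seq in annotation.sequences.items():
        lines.append(f"##sequence-region {name} 1 {len(seq)}")
    for g in annotation.genes:
        start1, end1 = g.start + 1, g.end  # 1-based inclusive
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join([g.chrom, _GFF_SOURCE, "gene", str(start1), str(end1), ".", g.strand, ".", attrs])
        )
        lines.append(
            "\t".join(
                [
                    g.chrom,
                    _GFF_SOURCE,
                    "mRNA",
                    str(start1),
                    str(end1),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}.t1;Parent={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, sequences: dict[str, str] | None = None) -> list[Gene]:
    """Read ``gene`` features from a GFF3 file into :class:`Gene` records.

    The 5' end of the feature (strand-dependent) is taken as the TSS.
    """
    genes: list[Gene] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9 or cols[2] != "gene":
            continue
        chrom, _, _, start1, end1, _, strand, _, attrs = cols
        gene_id = ""
        for kv in attrs.split(";"):
            k, _, v = kv.partition("=")
            if k == "ID":
                gene_id = v
        start, end = int(start1) - 1, int(end1)
        tss = start if strand == "+" else end - 1
        genes.append(Gene(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss, start=start, end=end))
    if sequences is not None:
        for g in genes:
            if g.chrom not in sequences:
                raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
    return genes


# ---------------------------------------------------------------------------
# BED6 (0-based half-open)

def write_bed6(intervals: Iterable[tuple[str, int, int, str, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) rows."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        c = line.split("\t")
        rows.append((c[0], int(c[1]), int(c[2]), c[3], int(float(c[4])), c[5]))
    return rows
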