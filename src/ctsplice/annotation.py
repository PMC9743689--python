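"""Gene-annotation model: genes, transcripts, exons, and derived introns.

This module turns a GTF or GFF3 file into an exact coordinate model used by
every downstream statistic.  All internal coordinates are 0-based, half-open
(BED convention); GTF/GFF3 input is 1-based inclusive and converted on read.
For each gene one *representative transcript* is selected — the transcript
with the largest spliced (summed-exon) length, with ties broken by the
lexicographically smallest transcript id — and introns are derived as the
gaps between its consecutive exons, numbered 1..n in the direction of
transcription regardless of genomic strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils
import pandas as pd

__all__ = [
    "AnnotationError",
    "Intron",
    "Transcript",
    "Gene",
    "GeneSet",
    "parse_gene_annotation",
    "select_representative_transcript",
    "derive_introns",
    "write_junction_table",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation input or invalid gene models."""


@dataclass(frozen=True)
class Intron:
    """One intron of a representative transcript.

    ``order`` is 1-based and runs 5'->3' in the direction of transcription.
    ``five_ss_pos`` is the genomic position (0-based) of the first intronic
    base in transcription direction, ``three_ss_pos`` of the last one.  The
    adjacent exonic positions used for splice-site ratios are exposed as
    ``exonic_5p_pos`` (last base of the upstream exon) and ``exonic_3p_pos``
    (first base of the downstream exon).
    """

    gene_id: str
    chrom: str
    strand: str
    order: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"intron {self.gene_id}:{self.order} has start >= end "
                f"({self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_ss_pos(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_ss_pos(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def exonic_5p_pos(self) -> int:
        """Genomic position of the exonic base adjacent to the 5' splice site."""
        return self.start - 1 if self.strand == "+" else self.end

    @property
    def exonic_3p_pos(self) -> int:
        """Genomic position of the exonic base adjacent to the 3' splice site."""
        return self.end if self.strand == "+" else self.start - 1


@dataclass(frozen=True)
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple  # tuple of (start, end), 0-based half-open, sorted

    def __post_init__(self) -> None:
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if not s < e:
                raise AnnotationError(
                    f"transcript {self.id}: exon ({s},{e}) has start >= end"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"transcript {self.id}: exons overlap or are unsorted at ({s},{e})"
                )
            prev_end = e

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple:
        return tuple(derive_introns(self))


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: dict = field(default_factory=dict)
    representative: Optional[str] = None

    def add_transcript(self, tx: Transcript) -> None:
        self.transcripts[tx.id] = tx

    @property
    def representative_transcript(self) -> Transcript:
        if self.representative is None:
            self.representative = select_representative_transcript(self).id
        return self.transcripts[self.representative]

    @property
    def span(self) -> tuple:
        starts = [tx.span[0] for tx in self.transcripts.values()]
        ends = [tx.span[1] for tx in self.transcripts.values()]
        return (min(starts), max(ends))


@dataclass
class GeneSet:
    """Ordered collection of genes with unique gene and transcript ids."""

    genes: dict = field(default_factory=dict)
    source_dialect: str = "GTF"

    def add_gene(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise AnnotationError(f"duplicate gene id {gene.id!r}")
        self.genes[gene.id] = gene

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def representative_introns(self) -> Iterator[Intron]:
        for gene in self:
            yield from gene.representative_transcript.introns

    def junction_table(self) -> pd.DataFrame:
        """One row per intron of each representative transcript."""
        rows = [
            {
                "gene": iv.gene_id,
                "chrom": iv.chrom,
                "strand": iv.strand,
                "order": iv.order,
                "start": iv.start,
                "end": iv.end,
                "five_ss_pos": iv.five_ss_pos,
                "three_ss_pos": iv.three_ss_pos,
            }
            for iv in self.representative_introns()
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "gene", "chrom", "strand", "order", "start", "end",
                "five_ss_pos", "three_ss_pos",
            ],
        )

    def write_gtf(self, path: str) -> None:
        """Write gene/transcript/exon records as GTF (1-based inclusive)."""
        with open(path, "w") as fh:
            for gene in self:
                gs, ge = gene.span
                fh.write(
                    f"{gene.chrom}\tctsplice\tgene\t{gs + 1}\t{ge}\t.\t"
                    f"{gene.strand}\t.\tgene_id \"{gene.id}\";\n"
                )
                for tx in gene.transcripts.values():
                    ts, te = tx.span
                    attrs = f'gene_id "{gene.id}"; transcript_id "{tx.id}";'
                    fh.write(
                        f"{gene.chrom}\tctsplice\ttranscript\t{ts + 1}\t{te}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
                    for s, e in tx.exons:
                        fh.write(
                            f"{gene.chrom}\tctsplice\texon\t{s + 1}\t{e}\t.\t"
                            f"{gene.strand}\t.\t{attrs}\n"
                        )


def select_representative_transcript(gene: Gene) -> Transcript:
    """Transcript with maximal spliced length; ties -> smallest transcript id."""
    if not gene.transcripts:
        raise AnnotationError(f"gene {gene.id!r} has no transcripts")
    return min(gene.transcripts.values(), key=lambda t: (-t.spliced_length, t.id))


def derive_introns(transcript: Transcript) -> list:
    """Introns as inter-exon gaps, ordered in transcription direction."""
    exons = transcript.exons
    gaps = []
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        if s1 < e0:
            raise AnnotationError(f"transcript {transcript.id}: overlapping exons")
        gaps.append((e0, s1))
    if transcript.strand == "-":
        gaps = gaps[::-1]
    return [
        Intron(
            gene_id=transcript.gene_id,
            chrom=transcript.chrom,
            strand=transcript.strand,
            order=i + 1,
            start=s,
            end=e,
        )
        for i, (s, e) in enumerate(gaps)
    ]


def write_junction_table(gene_set: GeneSet, path: str, bed_path: Optional[str] = None) -> None:
    """Write the per-intron TSV (and optionally a BED6 of intron intervals)."""
    table = gene_set.junction_table()
    table.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for row in table.itertuples(index=False):
                name = f"{row.gene}.intron{row.order}"
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n"
                )


def _validate_lines(path: str) -> tuple:
    """Light syntactic pre-scan.

    Returns (any feature line, gene feature seen, transcript feature seen).
    Errors name the offending 1-based line number, which gffutils does not
    report reliably.
    """
    has_features = False
    has_gene = has_tx = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise AnnotationError(
                    f"{path}: malformed record at line {lineno}: "
                    f"expected >=8 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: malformed record at line {lineno}: "
                    f"non-integer coordinates {fields[3]!r}, {fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}: malformed record at line {lineno}: "
                    f"invalid 1-based interval [{start}, {end}]"
                )
            has_features = True
            has_gene = has_gene or fields[2] == "gene"
            has_tx = has_tx or fields[2] in _TRANSCRIPT_TYPES
    return has_features, has_gene, has_tx


_TRANSCRIPT_TYPES = {"transcript", "mRNA", "mrna"}


def parse_gene_annotation(path: str, dialect: str = "GTF") -> GeneSet:
    """Parse a GTF or GFF3 file into a :class:`GeneSet`.

    Coordinates are converted from the 1-based inclusive source convention to
    the internal 0-based half-open one.  For GTF, gene/transcript features are
    inferred from exon attributes when absent; for GFF3, ID/Parent chains are
    followed.  Representative transcripts are selected eagerly.
    """
    dialect = dialect.upper()
    if dialect not in ("GTF", "GFF3"):
        raise ValueError(f"dialect must be GTF or GFF3, got {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    has_features, has_gene, has_tx = _validate_lines(path)
    if not has_features:
        return GeneSet(source_dialect=dialect)

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        verbose=False,
        disable_infer_genes=(dialect == "GFF3" or has_gene),
        disable_infer_transcripts=(dialect == "GFF3" or has_tx),
    )

    gene_set = GeneSet(source_dialect=dialect)
    seen_tx: set = set()

    for g in db.features_of_type("gene", order_by="start"):
        gene = Gene(id=g.id, chrom=g.seqid, strand=g.strand)
        for t in db.children(g, level=1):
            if t.featuretype not in _TRANSCRIPT_TYPES:
                continue
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(t, featuretype="exon")
            )
            if not exons:
                continue
            if t.id in seen_tx:
                raise AnnotationError(f"duplicate transcript id {t.id!r}")
            seen_tx.add(t.id)
            gene.add_transcript(
                Transcript(id=t.id, gene_id=g.id, chrom=g.seqid,
                           strand=g.strand, exons=tuple(exons))
            )
        if not gene.transcripts:
            continue
        gene.representative = select_representative_transcript(gene).id
        gene_set.add_gene(gene)

    # exons whose parent chain does not resolve to a transcript are an error
    n_exons_in_model = sum(
        len(tx.exons) for gene in gene_set for tx in gene.transcripts.values()
    )
    n_exons_in_file = len(list(db.features_of_type("exon")))
    if n_exons_in_file > n_exons_in_model:
        orphans = n_exons_in_file - n_exons_in_model
        raise AnnotationError(
            f"{path}: {orphans} exon record(s) without a resolvable parent transcript"
        )
    return gene_set
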