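"""Gene models, genomic intervals and GTF I/O.

Every stage of the pipeline shares the coordinate conventions defined here:
internally all intervals are 0-based half-open ``[start, end)``.  GTF input
(1-based, closed) is converted on read and back on write; BED-style intervals
pass through unchanged.  For a minus-strand gene the transcription start site
(TSS) is the *largest* transcribed coordinate and 5'->3' order runs toward
smaller genomic coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "IsoformModel",
    "GeneModel",
    "read_annotation",
    "write_annotation",
    "promoter_region",
    "gene_regions",
    "merge_intervals",
]

PROMOTER_UPSTREAM = 1000  # bp upstream of the TSS included in the promoter
PROMOTER_DOWNSTREAM = 1  # bp at/past the TSS included in the promoter


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)``, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class IsoformModel:
    """A single transcript isoform of a gene.

    ``exons`` are stored in transcription order (5'->3'); ``coding_class``
    distinguishes the full-length product from 5'-truncated short isoforms.
    """

    isoform_id: str
    gene_id: str
    exons: list[tuple[int, int]]
    coding_class: Literal["full-length", "truncated"] = "full-length"

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    """Exon/intron structure of one gene (union across its isoforms)."""

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    tss: int
    tts: int
    exons: list[tuple[int, int]]  # transcription order, union across isoforms
    isoforms: list[IsoformModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        genomic = self.exons_genomic()
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: exons overlap after union")

    def exons_genomic(self) -> list[tuple[int, int]]:
        """Union exons sorted by genomic coordinate."""
        return sorted(self.exons)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def genomic_length(self) -> int:
        return self.end - self.start

    @property
    def mrna_length(self) -> int:
        """Summed exon length of the canonical (longest) isoform.

        Falls back to the exon-union length for genes without isoform records.
        """
        if self.isoforms:
            return max(iso.transcript_length for iso in self.isoforms)
        return sum(e - s for s, e in self.exons)

    @property
    def exon_density(self) -> float:
        """Ratio of full mRNA length to genomic length (1 = intronless)."""
        return self.mrna_length / self.genomic_length

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and non-overlapping."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _to_transcription_order(
    intervals: Sequence[tuple[int, int]], strand: str
) -> list[tuple[int, int]]:
    ordered = sorted(intervals)
    return ordered if strand == "+" else ordered[::-1]


def read_annotation(path: str) -> dict[str, GeneModel]:
    """Parse a GTF file into ``GeneModel`` objects keyed by gene id.

    GTF 1-based closed coordinates become internal 0-based half-open ones.
    Exons of each transcript are collected under its ``gene_id``; the gene's
    own exon set is the union across isoforms, ordered 5'->3'.  Transcripts
    without exon records are skipped with a warning; malformed lines raise a
    parse error naming the offending line.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils reports the failing line in its message
        raise ValueError(f"malformed GTF {path}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for tx in db.features_of_type("transcript", order_by="start"):
        exons = [
            (ex.start - 1, ex.end)
            for ex in db.children(tx, featuretype="exon", order_by="start")
        ]
        if not exons:
            warnings.warn(
                f"transcript {tx.id} has no exons; skipped", stacklevel=2
            )
            continue
        gene_id = tx.attributes["gene_id"][0]
        strand = tx.strand
        iso = IsoformModel(
            isoform_id=tx.attributes.get("transcript_id", [tx.id])[0],
            gene_id=gene_id,
            exons=_to_transcription_order(exons, strand),
        )
        if gene_id not in genes:
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                chrom=tx.seqid,
                strand=strand,  # type: ignore[arg-type]
                tss=0,
                tts=0,
                exons=_to_transcription_order(exons, strand),
                isoforms=[iso],
            )
        else:
            g = genes[gene_id]
            g.isoforms.append(iso)
            union = merge_intervals(list(g.exons_genomic()) + exons)
            g.exons = _to_transcription_order(union, g.strand)

    for g in genes.values():
        _finalize_tss_tts(g)
        _classify_isoforms(g)
    return genes


def _finalize_tss_tts(g: GeneModel) -> None:
    if g.strand == "+":
        g.tss, g.tts = g.start, g.end - 1
    else:
        g.tss, g.tts = g.end - 1, g.start


def _classify_isoforms(g: GeneModel) -> None:
    """Mark all but the longest isoform(s) of a multi-isoform gene truncated."""
    if len(g.isoforms) < 2:
        return
    longest = max(iso.transcript_length for iso in g.isoforms)
    for iso in g.isoforms:
        iso.coding_class = (
            "full-length" if iso.transcript_length == longest else "truncated"
        )


def write_annotation(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models back to GTF (1-based closed), round-trip safe."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\ttedeff\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for iso in g.isoforms:
                iattrs = f'gene_id "{g.gene_id}"; transcript_id "{iso.isoform_id}";'
                ex_genomic = sorted(iso.exons)
                fh.write(
                    f"{g.chrom}\ttedeff\ttranscript\t{ex_genomic[0][0] + 1}\t"
                    f"{ex_genomic[-1][1]}\t.\t{g.strand}\t.\t{iattrs}\n"
                )
                for s, e in ex_genomic:
                    fh.write(
                        f"{g.chrom}\ttedeff\texon\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\t{iattrs}\n"
                    )


def promoter_region(g: GeneModel) -> GenomicInterval:
    """Strand-aware promoter window (-1000, +1) around the TSS.

    Covers 1000 bp upstream of the TSS plus the TSS base itself (1001 bp
    total), clipped at the chromosome start.
    """
    if g.strand == "+":
        start = max(0, g.tss - PROMOTER_UPSTREAM)
        end = g.tss + PROMOTER_DOWNSTREAM
    else:
        start = max(0, g.tss)
        end = g.tss + PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM
    return GenomicInterval(g.chrom, start, end, g.strand)


def gene_regions(
    g: GeneModel, which: Literal["promoter", "exons", "introns"]
) -> list[GenomicInterval]:
    """Promoter, union-exon or union-intron intervals of a gene.

    Introns are the genomic gaps between consecutive exons of the per-gene
    exon union; a single-exon gene has none.  Together exons and introns tile
    the TSS->TTS span exactly once.
    """
    if which == "promoter":
        return [promoter_region(g)]
    exons = merge_intervals(g.exons_genomic())
    if which == "exons":
        return [GenomicInterval(g.chrom, s, e, g.strand) for s, e in exons]
    if which == "introns":
        return [
            GenomicInterval(g.chrom, e1, s2, g.strand)
            for (_, e1), (s2, _) in zip(exons, exons[1:])
            if s2 > e1
        ]
    raise ValueError(f"unknown region kind {which!r}")
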