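"""Gene annotation model with flattened exon counting bins.

A gene's transcripts usually share most of their exonic sequence, so
exon-level differential analysis does not operate on annotated exons
directly.  Instead each gene is *flattened* into disjoint counting bins:
maximal intervals over which the set of covering transcripts is constant.
A bin covered by exactly one transcript is *transcript-specific*
(a discriminating exon): differential usage of such a bin implicates that
splice variant uniquely, which is the unit the evaluation rules in
:mod:`splicebench.evaluation` are built on.

Coordinates are 0-based half-open internally; GTF I/O is 1-based closed.
Strand never affects binning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

Interval = Tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;?')


class GTFParseError(ValueError):
    """Raised for a malformed GTF record; the message names the line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExonBin:
    """A maximal interval within a gene covered by a fixed transcript set."""

    gene_id: str
    chrom: str
    start: int
    end: int
    member_transcripts: frozenset

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"bin {self.start}-{self.end} has length < 1")
        if not self.member_transcripts:
            raise ValueError("bin with empty transcript membership")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_transcript_specific(self) -> bool:
        return len(self.member_transcripts) == 1

    @property
    def bin_id(self) -> str:
        return f"{self.gene_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class TranscriptModel:
    """A splice variant: an ordered set of non-overlapping exon intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end <= start:
                raise ValueError(
                    f"{self.transcript_id}: empty exon interval [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons at {start}"
                )
            prev_end = end
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def n_junctions(self) -> int:
        return len(self.exons) - 1

    def junction_positions(self) -> List[int]:
        """Transcript-coordinate positions of internal exon-exon junctions.

        Position j means the junction lies between spliced bases j-1 and j.
        """
        positions, acc = [], 0
        for start, end in self.exons[:-1]:
            acc += end - start
            positions.append(acc)
        return positions


@dataclass
class GeneModel:
    """A gene: a bag of transcripts plus derived counting bins."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)

    @cached_property
    def bins(self) -> List[ExonBin]:
        return flatten_gene(self)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)


@dataclass
class GenomeAnnotation:
    """All genes of a (toy or real) genome annotation."""

    genes: Dict[str, GeneModel]
    source_coordinate_system: str = "0-based half-open"

    def transcripts(self) -> Iterator[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def get_transcript(self, transcript_id: str) -> TranscriptModel:
        for gene in self.genes.values():
            if transcript_id in gene.transcripts:
                return gene.transcripts[transcript_id]
        raise KeyError(f"unknown transcript_id {transcript_id!r}")

    def bins(self) -> Iterator[ExonBin]:
        for gene_id in sorted(self.genes):
            yield from self.genes[gene_id].bins

    @cached_property
    def bins_by_id(self) -> Dict[str, ExonBin]:
        return {b.bin_id: b for b in self.bins()}

    def transcript_bins(self, transcript_id: str) -> List[ExonBin]:
        tx = self.get_transcript(transcript_id)
        gene = self.genes[tx.gene_id]
        return [b for b in gene.bins if transcript_id in b.member_transcripts]


def flatten_gene(gene: GeneModel) -> List[ExonBin]:
    """Partition the exonic footprint of a gene into counting bins.

    Every exon boundary of every transcript splits the genome; within each
    elementary interval between consecutive boundaries the covering
    transcript set is constant, so membership can be decided per interval.
    Adjacent intervals with identical membership are merged back, giving
    maximal disjoint bins that exactly cover the union of exon bases.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    bounds = sorted(
        {b for tx in gene.transcripts.values() for ex in tx.exons for b in ex}
    )
    raw: List[Tuple[int, int, frozenset]] = []
    for start, end in zip(bounds, bounds[1:]):
        members = frozenset(
            tx.transcript_id
            for tx in gene.transcripts.values()
            if any(es <= start and end <= ee for es, ee in tx.exons)
        )
        if members:
            raw.append((start, end, members))
    merged: List[List] = []
    for start, end, members in raw:
        if merged and merged[-1][1] == start and merged[-1][2] == members:
            merged[-1][1] = end
        else:
            merged.append([start, end, members])
    return [
        ExonBin(gene.gene_id, gene.chrom, s, e, m) for s, e, m in merged
    ]


def transcript_specific_bins(
    gene: GeneModel, transcript_id: str
) -> List[ExonBin]:
    """Bins belonging to exactly this splice variant (discriminating exons)."""
    if transcript_id not in gene.transcripts:
        raise KeyError(
            f"transcript {transcript_id!r} not in gene {gene.gene_id!r}"
        )
    return [
        b for b in gene.bins if b.member_transcripts == frozenset({transcript_id})
    ]


def load_annotation(gtf_path) -> GenomeAnnotation:
    """Parse a GTF file (Ensembl/UCSC attribute dialect) into the model.

    Only ``exon`` records are used; gene and transcript structure is derived
    from their ``gene_id``/``transcript_id`` attributes.  1-based closed GTF
    coordinates are converted to 0-based half-open.
    """
    exons: Dict[str, List[Interval]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frm, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if start < 1 or end < start:
                raise GTFParseError(
                    f"{gtf_path}: line {lineno}: invalid interval {start}-{end}"
                )
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr:
                raise GTFParseError(
                    f"{gtf_path}: line {lineno}: exon record lacks transcript_id"
                )
            if "gene_id" not in attr:
                raise GTFParseError(
                    f"{gtf_path}: line {lineno}: exon record lacks gene_id"
                )
            tid = attr["transcript_id"]
            record_meta = (attr["gene_id"], chrom, strand)
            if tid in meta and meta[tid] != record_meta:
                raise GTFParseError(
                    f"{gtf_path}: line {lineno}: transcript {tid!r} has "
                    "inconsistent gene/chrom/strand across exon records"
                )
            meta.setdefault(tid, record_meta)
            exons.setdefault(tid, []).append((start - 1, end))

    genes: Dict[str, GeneModel] = {}
    for tid in sorted(exons):
        gene_id, chrom, strand = meta[tid]
        tx = TranscriptModel(tid, gene_id, chrom, strand, tuple(exons[tid]))
        gene = genes.setdefault(gene_id, GeneModel(gene_id, chrom, strand))
        gene.transcripts[tid] = tx
    return GenomeAnnotation(genes=genes)


def write_gtf(annotation: GenomeAnnotation, path, source: str = "splicebench") -> None:
    """Write exon records, converting back to 1-based closed coordinates."""
    with open(path, "w") as out:
        for gene_id in sorted(annotation.genes):
            gene = annotation.genes[gene_id]
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                for i, (start, end) in enumerate(tx.exons, start=1):
                    attrs = (
                        f'gene_id "{gene_id}"; transcript_id "{tid}"; '
                        f'exon_number "{i}";'
                    )
                    out.write(
                        "\t".join(
                            [
                                tx.chrom,
                                source,
                                "exon",
                                str(start + 1),
                                str(end),
                                ".",
                                tx.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def write_bins_bed(annotation: GenomeAnnotation, path) -> int:
    """Write all counting bins as BED6 (name = gene|members, score = |members|)."""
    n = 0
    with open(path, "w") as out:
        for b in annotation.bins():
            strand = annotation.genes[b.gene_id].strand
            name = f"{b.gene_id}|{','.join(sorted(b.member_transcripts))}"
            out.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{name}\t"
                f"{len(b.member_transcripts)}\t{strand}\n"
            )
            n += 1
    return n


def spliced_sequence(transcript: TranscriptModel, fasta) -> str:
    """Spliced (mature) sequence of a transcript from an indexed FASTA.

    ``fasta`` is a :class:`pyfaidx.Fasta`-like mapping of chrom ->
    sliceable sequence.  Minus-strand transcripts are reverse-complemented.
    """
    seq = "".join(
        str(fasta[transcript.chrom][start:end]) for start, end in transcript.exons
    ).upper()
    if transcript.strand == "-":
        seq = reverse_complement(seq)
    return seq
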