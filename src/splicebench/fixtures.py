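"""Toy reference, annotation, background counts and background reads.

Everything the benchmark pipeline consumes can be generated here at desk
scale: a random genome with multi-isoform genes, a null background count
matrix (negative-binomial per counting bin, equal means in the C and T
groups, so no bin is truly differential), and background FASTQ reads drawn
from transcripts proportionally to those counts.  The generated truth is
persisted in a manifest so tests never read structure out of code constants.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    spliced_sequence,
    write_gtf,
)
from .selection import CountsMatrix
from .simulate import SpikePlan, emit_fastq, random_reads

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureConfig:
    """Knobs for the toy genome and the null background.

    Defaults describe a 20-gene locus with 1-5 isoforms per gene, exons of
    100-250 nt, and a 5+5 replicate design with overdispersed background
    counts (NB dispersion 0.1, per-bin means ~30) — small enough to run in
    seconds yet structured enough that every pipeline stage has work to do.
    """

    n_genes: int = 20
    isoforms_per_gene: Tuple[int, int] = (1, 5)
    exons_per_gene: Tuple[int, int] = (3, 8)
    exon_length: Tuple[int, int] = (100, 250)
    intron_length: Tuple[int, int] = (60, 200)
    intergenic_gap: int = 500
    n_samples_per_group: int = 5
    bg_mean: float = 30.0
    dispersion: float = 0.1
    cassette_prob: float = 0.8
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("isoforms_per_gene", "exons_per_gene", "exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range must be positive and ordered")
        if self.n_genes < 0 or self.intergenic_gap < 1:
            raise ValueError("n_genes must be >= 0 and intergenic_gap positive")
        if self.bg_mean < 0 or self.dispersion < 0:
            raise ValueError("bg_mean and dispersion must be >= 0")
        if not 0 <= self.cassette_prob <= 1:
            raise ValueError("cassette_prob must lie in [0, 1]")

    @property
    def sample_ids(self) -> List[str]:
        n = self.n_samples_per_group
        return [f"C{i}" for i in range(1, n + 1)] + [f"T{i}" for i in range(1, n + 1)]

    @property
    def group_of(self) -> Dict[str, str]:
        return {s: s[0] for s in self.sample_ids}


@dataclass
class ReferenceManifest:
    """Generated truth for a toy reference: what was written and where."""

    fasta: str
    gtf: str
    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame
    annotation: GenomeAnnotation

    def write(self, out_dir) -> Dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name, frame in (
            ("genes", self.genes),
            ("transcripts", self.transcripts),
            ("exons", self.exons),
        ):
            path = os.path.join(out_dir, f"manifest_{name}.tsv")
            frame.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def _isoform_exon_subsets(
    n_exons: int,
    n_isoforms: int,
    cassette_prob: float,
    rng: np.random.Generator,
) -> List[Tuple[int, ...]]:
    """Choose distinct exon subsets, one per isoform.

    Each isoform keeps each gene exon with probability 0.7 (cassette-like
    skipping) and at least two exons overall, so spliced lengths stay long
    enough to carry a 150 nt fragment; a single-isoform gene keeps all
    exons.  With probability ``cassette_prob`` a multi-isoform gene gets a
    planted cassette exon private to one isoform — the discriminating-exon
    structure that makes a splice variant identifiable at exon level.
    """
    if n_isoforms == 1:
        return [tuple(range(n_exons))]
    marker = owner = None
    if rng.random() < cassette_prob:
        marker = int(rng.integers(n_exons))
        owner = int(rng.integers(n_isoforms))
    subsets: List[Tuple[int, ...]] = []
    attempts = 0
    while len(subsets) < n_isoforms and attempts < 50 * n_isoforms:
        attempts += 1
        keep = {i for i in range(n_exons) if rng.random() < 0.7}
        if marker is not None:
            if len(subsets) == owner:
                keep.add(marker)
            else:
                keep.discard(marker)
        subset = tuple(sorted(keep))
        if len(subset) >= 2 and subset not in subsets:
            subsets.append(subset)
    return subsets or [tuple(range(n_exons))]


def make_toy_reference(
    config: FixtureConfig, out_fasta, out_gtf
) -> ReferenceManifest:
    """Write a seeded random FASTA + GTF pair and return the manifest."""
    rng = np.random.default_rng([config.seed, 0])
    genes: Dict[str, GeneModel] = {}
    gene_rows, tx_rows, exon_rows = [], [], []
    cursor = 0
    for g in range(1, config.n_genes + 1):
        cursor += config.intergenic_gap
        gene_id = f"gene{g:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons: List[Tuple[int, int]] = []
        for _ in range(n_exons):
            length = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
            exons.append((cursor, cursor + length))
            cursor += length + int(
                rng.integers(config.intron_length[0], config.intron_length[1] + 1)
            )
        n_iso = int(
            rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1)
        )
        gene = GeneModel(gene_id, config.chrom, strand)
        subsets = _isoform_exon_subsets(n_exons, n_iso, config.cassette_prob, rng)
        for k, subset in enumerate(subsets, start=1):
            tid = f"{gene_id}.t{k}"
            tx = TranscriptModel(
                tid, gene_id, config.chrom, strand, tuple(exons[i] for i in subset)
            )
            gene.transcripts[tid] = tx
            tx_rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene_id,
                    "n_exons": len(tx.exons),
                    "spliced_length": tx.spliced_length,
                }
            )
            for start, end in tx.exons:
                exon_rows.append(
                    {
                        "transcript_id": tid,
                        "gene_id": gene_id,
                        "chrom": config.chrom,
                        "start": start,
                        "end": end,
                    }
                )
        genes[gene_id] = gene
        gene_rows.append(
            {
                "gene_id": gene_id,
                "chrom": config.chrom,
                "strand": strand,
                "n_transcripts": gene.n_transcripts,
            }
        )
    annotation = GenomeAnnotation(genes=genes)

    total_len = cursor + config.intergenic_gap
    with open(out_fasta, "w") as out:
        if config.n_genes > 0:
            seq = "".join(_BASES[rng.integers(0, 4, size=total_len)])
            out.write(f">{config.chrom}\n")
            for i in range(0, total_len, 60):
                out.write(seq[i : i + 60] + "\n")
    write_gtf(annotation, out_gtf)
    empty_cols = {
        "genes": ["gene_id", "chrom", "strand", "n_transcripts"],
        "transcripts": ["transcript_id", "gene_id", "n_exons", "spliced_length"],
        "exons": ["transcript_id", "gene_id", "chrom", "start", "end"],
    }
    return ReferenceManifest(
        fasta=str(out_fasta),
        gtf=str(out_gtf),
        genes=pd.DataFrame(gene_rows, columns=empty_cols["genes"]),
        transcripts=pd.DataFrame(tx_rows, columns=empty_cols["transcripts"]),
        exons=pd.DataFrame(exon_rows, columns=empty_cols["exons"]),
        annotation=annotation,
    )


def _bin_counts(
    config: FixtureConfig, n_bins: int, rng: np.random.Generator
) -> np.ndarray:
    """Null NB counts, bins x samples: per-bin means shared by both groups."""
    n_samples = 2 * config.n_samples_per_group
    means = config.bg_mean * rng.uniform(0.5, 1.5, size=n_bins)
    if config.dispersion == 0:
        return rng.poisson(means[:, None], size=(n_bins, n_samples))
    n = 1.0 / config.dispersion
    p = n / (n + means)
    return rng.negative_binomial(n, p[:, None], size=(n_bins, n_samples))


def make_background(
    config: FixtureConfig,
    annotation: GenomeAnnotation,
    reference_fasta,
    out_dir,
    read_plan: Optional[SpikePlan] = None,
) -> Tuple[CountsMatrix, Dict[str, Tuple[str, str]]]:
    """Null background counts plus per-sample paired FASTQ reads.

    Counts are negative-binomial per bin with identical group means, so no
    feature is differentially expressed by construction.  Per sample, each
    transcript contributes reads proportional to the mean count of its bins
    in that sample, with seeded random fragment starts.
    """
    import pyfaidx

    rng = np.random.default_rng([config.seed, 1])
    plan = read_plan or SpikePlan(seed=config.seed)
    os.makedirs(out_dir, exist_ok=True)
    bins = list(annotation.bins())
    values = pd.DataFrame(
        _bin_counts(config, len(bins), rng) if bins else
        np.empty((0, 2 * config.n_samples_per_group), dtype=np.int64),
        index=[b.bin_id for b in bins],
        columns=config.sample_ids,
        dtype=np.int64,
    )
    counts = CountsMatrix(values, config.group_of)

    sequences: Dict[str, str] = {}
    if config.n_genes > 0 and bins:
        fasta = pyfaidx.Fasta(str(reference_fasta))
        for tx in annotation.transcripts():
            sequences[tx.transcript_id] = spliced_sequence(tx, fasta)

    fastqs: Dict[str, Tuple[str, str]] = {}
    for sample in config.sample_ids:
        pairs = []
        for tx in annotation.transcripts():
            tx_bins = annotation.transcript_bins(tx.transcript_id)
            weight = float(
                np.mean([values.loc[b.bin_id, sample] for b in tx_bins])
            ) if tx_bins else 0.0
            n_reads = int(round(weight))
            if n_reads == 0:
                continue
            if tx.spliced_length < plan.fragment_length:
                logger.warning(
                    "skipping background reads for short transcript %s",
                    tx.transcript_id,
                )
                continue
            pairs.extend(
                random_reads(tx, sequences[tx.transcript_id], n_reads, plan, rng)
            )
        p1 = os.path.join(out_dir, f"{sample}_R1.fastq")
        p2 = os.path.join(out_dir, f"{sample}_R2.fastq")
        emit_fastq(pairs, plan, p1, p2, prefix="bg")
        fastqs[sample] = (p1, p2)
    return counts, fastqs
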