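import collections

import pytest

from splicebench.annotation import GeneModel, TranscriptModel, load_annotation
from splicebench.fixtures import FixtureConfig, make_background, make_toy_reference

ToyBundle = collections.namedtuple(
    "ToyBundle", "config manifest annotation counts fastqs dir"
)


def make_gene(gene_id, exons_by_transcript, chrom="chr1", strand="+"):
    """Hand-build a GeneModel from {tid: [(start, end), ...]}."""
    gene = GeneModel(gene_id, chrom, strand)
    for tid, exons in exons_by_transcript.items():
        gene.transcripts[tid] = TranscriptModel(
            tid, gene_id, chrom, strand, tuple(exons)
        )
    return gene


def build_bundle(tmp_dir, **config_kwargs):
    config = FixtureConfig(**config_kwargs)
    manifest = make_toy_reference(
        config, str(tmp_dir / "reference.fa"), str(tmp_dir / "annotation.gtf")
    )
    annotation = load_annotation(manifest.gtf)
    counts, fastqs = make_background(
        config, annotation, manifest.fasta, str(tmp_dir / "background")
    )
    return ToyBundle(config, manifest, annotation, counts, fastqs, tmp_dir)


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """A 20-gene reference with null background counts and reads."""
    return build_bundle(tmp_path_factory.mktemp("toy"), n_genes=20, seed=11)


@pytest.fixture(scope="session")
def rich_bundle(tmp_path_factory):
    """A 40-gene, all-multi-isoform reference for selection/recovery tests."""
    return build_bundle(
        tmp_path_factory.mktemp("rich"),
        n_genes=40,
        isoforms_per_gene=(3, 5),
        seed=1,
    )
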