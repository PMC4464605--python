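"""Spike-in candidate selection over an annotation and a background count matrix.

The true-positive candidates for a splicing benchmark are transcripts that
(a) come from genes with several splice variants, (b) carry at least one
discriminating (transcript-specific) counting bin, and (c) show enough
background signal on those bins that a caller could in principle see them.
The chain is applied gene-wise with an audit of survivors per stage, and a
seeded sampler then picks one transcript per gene for the spike plan.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, transcript_specific_bins

VALID_GROUPS = ("C", "T")


class CountsMatrix:
    """Non-negative integer counts, features x samples, with a C/T grouping."""

    def __init__(self, values: pd.DataFrame, group_of: Mapping[str, str]):
        arr = values.to_numpy()
        if arr.size and (np.asarray(arr, dtype=float) < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.size and not np.all(np.mod(np.asarray(arr, dtype=float), 1) == 0):
            raise ValueError("counts must be integral")
        missing = [s for s in values.columns if s not in group_of]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        bad = {s: g for s, g in group_of.items() if g not in VALID_GROUPS}
        if bad:
            raise ValueError(f"groups must be one of {VALID_GROUPS}: {bad}")
        self.values = values.astype(np.int64)
        self.group_of = {s: group_of[s] for s in values.columns}

    @property
    def feature_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> List[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def group_means(self) -> pd.DataFrame:
        return pd.DataFrame(
            {g: self.values[self.samples_in_group(g)].mean(axis=1) for g in VALID_GROUPS}
        )

    def to_tsv(self, path) -> None:
        self.values.rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, group_of: Optional[Mapping[str, str]] = None) -> "CountsMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        if group_of is None:
            # samples named like C1..C5 / T1..T5: group is the leading letter
            group_of = {s: s[0] for s in values.columns}
        return cls(values, group_of)


class Candidate(NamedTuple):
    gene_id: str
    transcript_id: str
    discriminating_bins: Tuple[str, ...]


@dataclass
class CandidateSet:
    """Survivors of the selection chain plus the per-stage audit counts."""

    stage_counts: "OrderedDict[str, int]"
    candidates: List[Candidate]

    @property
    def gene_ids(self) -> List[str]:
        return sorted({c.gene_id for c in self.candidates})

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            for stage, count in self.stage_counts.items():
                out.write(f"# stage {stage}: {count} genes\n")
            out.write("gene_id\ttranscript_id\tdiscriminating_bins\n")
            for c in sorted(self.candidates):
                out.write(
                    f"{c.gene_id}\t{c.transcript_id}\t"
                    f"{','.join(c.discriminating_bins)}\n"
                )


def select_candidates(
    annotation: GenomeAnnotation,
    counts: CountsMatrix,
    min_isoforms: int = 3,
    min_discriminating_total: int = 10,
) -> CandidateSet:
    """Apply the candidate-selection chain.

    Stages (gene-level survivor counts are recorded after each):

    1. keep genes with at least ``min_isoforms`` splice variants;
    2. keep genes with at least one transcript owning a transcript-specific
       counting bin;
    3. drop transcripts whose transcript-specific bins sum to fewer than
       ``min_discriminating_total`` counts over ALL samples of both groups
       (a total of exactly the threshold passes); a gene survives if at
       least one of its transcripts does.
    """
    known_bins = set(annotation.bins_by_id)
    unknown = [f for f in counts.feature_ids if f not in known_bins]
    if unknown:
        raise ValueError(
            f"count features absent from annotation bins: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    totals = counts.values.sum(axis=1)  # per-bin total over C1..Cn, T1..Tn

    stage_counts: "OrderedDict[str, int]" = OrderedDict()
    stage_counts["input"] = len(annotation.genes)

    stage1 = [
        g for g in sorted(annotation.genes)
        if annotation.genes[g].n_transcripts >= min_isoforms
    ]
    stage_counts["min_isoforms"] = len(stage1)

    specific: Dict[str, Dict[str, Tuple[str, ...]]] = {}
    for gene_id in stage1:
        gene = annotation.genes[gene_id]
        per_tx = {}
        for tid in sorted(gene.transcripts):
            bins = transcript_specific_bins(gene, tid)
            if bins:
                per_tx[tid] = tuple(b.bin_id for b in bins)
        if per_tx:
            specific[gene_id] = per_tx
    stage_counts["has_specific_bin"] = len(specific)

    candidates: List[Candidate] = []
    surviving_genes = set()
    for gene_id, per_tx in specific.items():
        for tid, bin_ids in per_tx.items():
            total = int(sum(totals.get(b, 0) for b in bin_ids))
            if total >= min_discriminating_total:
                candidates.append(Candidate(gene_id, tid, bin_ids))
                surviving_genes.add(gene_id)
    stage_counts["min_discriminating_counts"] = len(surviving_genes)

    return CandidateSet(stage_counts=stage_counts, candidates=sorted(candidates))


def pick_spike_transcripts(
    candidates: CandidateSet, n: int, seed: int
) -> List[Tuple[str, str]]:
    """Seeded random pick of ``n`` candidate genes, one transcript each.

    Replaces manual curation of candidates with a reproducible sample
    without replacement; candidates are ordered by gene id before sampling
    so the result depends only on the seed and the candidate set.
    """
    by_gene: Dict[str, List[str]] = {}
    for c in candidates.candidates:
        by_gene.setdefault(c.gene_id, []).append(c.transcript_id)
    genes = sorted(by_gene)
    if n > len(genes):
        raise ValueError(f"requested {n} spike genes but only {len(genes)} candidates")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(genes), size=n, replace=False)
    picks = []
    for idx in sorted(chosen):
        gene_id = genes[idx]
        tids = sorted(by_gene[gene_id])
        picks.append((gene_id, tids[int(rng.integers(len(tids)))]))
    return picks
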