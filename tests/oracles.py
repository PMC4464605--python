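"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-base enumeration, O(n^2) scans)
and shares no code path with the package beyond its public data types.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

import numpy as np


def brute_force_bins(gene) -> List[Tuple[int, int, frozenset]]:
    """Per-base transcript membership, merged into maximal runs."""
    base_members: Dict[int, Set[str]] = {}
    for tx in gene.transcripts.values():
        for start, end in tx.exons:
            for pos in range(start, end):
                base_members.setdefault(pos, set()).add(tx.transcript_id)
    runs: List[List] = []
    for pos in sorted(base_members):
        members = frozenset(base_members[pos])
        if runs and runs[-1][1] == pos and runs[-1][2] == members:
            runs[-1][1] = pos + 1
        else:
            runs.append([pos, pos + 1, members])
    return [(s, e, m) for s, e, m in runs]


def brute_force_specific_bins(gene, transcript_id: str) -> List[Tuple[int, int]]:
    return [
        (s, e)
        for s, e, members in brute_force_bins(gene)
        if members == frozenset({transcript_id})
    ]


def brute_force_bh(pvalues: Sequence[float]) -> List[float]:
    """Step-up BH by definition: adj_i = min over p_(k) >= p_i of p_(k)*n/k."""
    p = list(pvalues)
    n = len(p)
    sp = sorted(p)
    out = []
    for pi in p:
        candidates = [sp[k] * n / (k + 1) for k in range(n) if sp[k] >= pi]
        out.append(min(1.0, min(candidates)))
    return out


def brute_force_select(
    annotation, counts_df, min_isoforms: int, min_discriminating_total: int
):
    """Naive per-gene re-evaluation of the candidate chain.

    Returns (stage_counts dict, set of (gene_id, transcript_id)).
    """
    n_input = len(annotation.genes)
    stage1 = [
        gid
        for gid in annotation.genes
        if len(annotation.genes[gid].transcripts) >= min_isoforms
    ]
    stage2, survivors = [], set()
    stage3_genes = set()
    for gid in stage1:
        gene = annotation.genes[gid]
        with_specific = {
            tid: brute_force_specific_bins(gene, tid)
            for tid in gene.transcripts
            if brute_force_specific_bins(gene, tid)
        }
        if not with_specific:
            continue
        stage2.append(gid)
        for tid, bins in with_specific.items():
            total = 0
            for s, e in bins:
                bin_id = f"{gid}:{s}-{e}"
                if bin_id in counts_df.index:
                    total += int(counts_df.loc[bin_id].sum())
            if total >= min_discriminating_total:
                survivors.add((gid, tid))
                stage3_genes.add(gid)
    stage_counts = {
        "input": n_input,
        "min_isoforms": len(stage1),
        "has_specific_bin": len(stage2),
        "min_discriminating_counts": len(stage3_genes),
    }
    return stage_counts, survivors


def pileup_mates(pairs, spliced_length: int, read_length: int, fragment_length: int):
    """Per-base mate coverage over transcript coordinates."""
    cov = np.zeros(spliced_length, dtype=int)
    for p in pairs:
        s = p.fragment_start
        cov[s : s + read_length] += 1
        cov[s + fragment_length - read_length : s + fragment_length] += 1
    return cov


def mates_spanning(pairs, junction: int, read_length: int, fragment_length: int) -> int:
    """Number of mates covering both bases junction-1 and junction."""
    n = 0
    for p in pairs:
        m1 = (p.fragment_start, p.fragment_start + read_length)
        m2_start = p.fragment_start + fragment_length - read_length
        m2 = (m2_start, m2_start + read_length)
        for lo, hi in (m1, m2):
            if lo <= junction - 1 and junction < hi:
                n += 1
    return n


def brute_force_exon_calls(
    annotation, adjusted: Dict[str, float], alpha: float
) -> Set[str]:
    """Transcript calls by scanning every gene's bins directly."""
    called = set()
    for gene in annotation.genes.values():
        for s, e, members in brute_force_bins(gene):
            bin_id = f"{gene.gene_id}:{s}-{e}"
            if len(members) == 1 and adjusted.get(bin_id, 1.0) <= alpha:
                called.add(next(iter(members)))
    return called
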