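"""Transcript detection filter and pairwise detected-set overlap matrix.

A transcript counts as *detected* in a quantification run when its FPKM
exceeds 0.1 and its average per-base coverage exceeds 0 (both strictly).
Detected sets from different library preparations are compared with a
row-normalised overlap matrix: entry (i, j) is the percentage of set i's
transcripts also found in set j, which is deliberately asymmetric — a
small set can sit almost entirely inside a large one while covering only
a fraction of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QuantRecord:
    transcript_id: str
    fpkm: float
    coverage: float

    def __post_init__(self) -> None:
        if self.fpkm < 0 or self.coverage < 0:
            raise ValueError(
                f"{self.transcript_id}: FPKM and coverage must be >= 0"
            )


@dataclass
class DetectedSet:
    label: str
    transcript_ids: Set[str]

    def __len__(self) -> int:
        return len(self.transcript_ids)


def read_quant_tsv(path) -> List[QuantRecord]:
    """Read a Cufflinks-style quantification table (transcript_id, FPKM,
    coverage; column names case-insensitive)."""
    frame = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in frame.columns}
    try:
        tid_col, fpkm_col, cov_col = (
            cols["transcript_id"],
            cols["fpkm"],
            cols["coverage"],
        )
    except KeyError as exc:
        raise ValueError(
            f"{path}: expected columns transcript_id, FPKM, coverage"
        ) from exc
    return [
        QuantRecord(str(r[tid_col]), float(r[fpkm_col]), float(r[cov_col]))
        for _, r in frame.iterrows()
    ]


def detect_transcripts(
    records: Sequence[QuantRecord],
    fpkm_min: float = 0.1,
    coverage_min: float = 0.0,
    label: str = "detected",
) -> DetectedSet:
    """Apply the strict FPKM > fpkm_min AND coverage > coverage_min filter."""
    seen = set()
    for rec in records:
        if rec.transcript_id in seen:
            raise ValueError(f"duplicate quantification for {rec.transcript_id!r}")
        seen.add(rec.transcript_id)
    kept = {
        rec.transcript_id
        for rec in records
        if rec.fpkm > fpkm_min and rec.coverage > coverage_min
    }
    return DetectedSet(label=label, transcript_ids=kept)


def overlap_matrix(sets: Sequence[DetectedSet]) -> pd.DataFrame:
    """Row-normalised percentage overlap between detected sets.

    Entry (i, j) = 100 * |S_i intersect S_j| / |S_i|; the diagonal is 100
    for non-empty sets and rows for empty sets are NaN (not available).
    """
    if len(sets) < 2:
        raise ValueError("need at least two detected sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("detected-set labels must be unique")
    mat = np.full((len(sets), len(sets)), np.nan)
    for i, si in enumerate(sets):
        if not si.transcript_ids:
            continue
        for j, sj in enumerate(sets):
            mat[i, j] = 100.0 * len(si.transcript_ids & sj.transcript_ids) / len(si)
    return pd.DataFrame(mat, index=labels, columns=labels)


def write_overlap_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("set").to_csv(path, sep="\t", float_format="%.2f", na_rep="NA")


def plot_overlap_heatmap(matrix: pd.DataFrame, path) -> None:
    """Optional heatmap of the overlap matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix), 1 + 0.6 * len(matrix)))
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=100, cmap="RdYlGn_r")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    fig.colorbar(im, ax=ax, label="% shared transcripts")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
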