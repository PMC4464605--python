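"""Scoring caller output against the spike-in truth table.

Two calling conventions are supported, mirroring how splicing callers
report results.  Transcript-level callers (Cuffdiff- or EBSeq-like tables)
give one q-value per transcript: a transcript is differentially expressed
at q <= alpha (inclusive).  Exon-level callers (DEXSeq-like tables) give a
p-value per counting bin: a transcript is called when at least one of its
*transcript-specific* bins is significant after Benjamini-Hochberg
adjustment — a significant bin shared by several splice variants implicates
none of them uniquely and never triggers a call.  Calls are then reduced
against the truth table to TP/FP counts, a detection percentage and the
realized false discovery rate, and MA statistics (mean log2 fold change vs
mean log10 abundance) summarise the injected signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation
from .selection import CountsMatrix
from .simulate import TruthTable

LEVELS = ("transcript", "exon")


@dataclass
class CallerResult:
    """A generic caller table: one score per feature.

    At transcript level the score is a q-value; at exon level it is a
    p-value per counting bin, either raw (``adjusted=False``, adjusted here
    before calling) or already FDR-adjusted.
    """

    level: str
    scores: pd.Series  # feature_id -> score
    adjusted: bool = True
    provenance: str = "caller"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        vals = self.scores.to_numpy(dtype=float)
        if vals.size and (np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any()):
            raise ValueError("scores must lie in [0, 1]")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate feature ids in caller result")

    @classmethod
    def from_tsv(cls, path, level: str, adjusted: bool = True,
                 provenance: str = "caller") -> "CallerResult":
        frame = pd.read_csv(path, sep="\t")
        return cls(
            level=level,
            scores=pd.Series(
                frame.iloc[:, 1].to_numpy(dtype=float),
                index=frame.iloc[:, 0].astype(str),
            ),
            adjusted=adjusted,
            provenance=provenance,
        )

    def to_tsv(self, path) -> None:
        self.scores.rename("score").rename_axis("feature_id").to_csv(path, sep="\t")


@dataclass
class CallSet:
    called_transcripts: Set[str]
    alpha: float
    provenance: str = "caller"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    n_truth: int
    detection_pct: float
    realized_fdr: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "n_truth": self.n_truth,
            "detection_pct": self.detection_pct,
            "realized_fdr": self.realized_fdr,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as out:
            json.dump(self.to_dict(), out, indent=2)
            out.write("\n")


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return []
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(q) for q in adjusted]


def call_from_transcript_level(result: CallerResult, alpha: float = 0.05) -> CallSet:
    """Call transcripts with q-value <= alpha (inclusive)."""
    if result.level != "transcript":
        raise ValueError("call_from_transcript_level needs a transcript-level result")
    called = {str(t) for t, q in result.scores.items() if q <= alpha}
    return CallSet(called, alpha=alpha, provenance=result.provenance)


def call_from_exon_level(
    result: CallerResult,
    annotation: GenomeAnnotation,
    alpha: float = 0.05,
) -> CallSet:
    """Call a transcript when >=1 of its transcript-specific bins is
    significant after BH adjustment; shared bins never trigger a call."""
    if result.level != "exon":
        raise ValueError("call_from_exon_level needs an exon-level result")
    bins_by_id = annotation.bins_by_id
    unknown = [f for f in result.scores.index if f not in bins_by_id]
    if unknown:
        raise ValueError(
            f"exon features absent from annotation bins: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    scores = result.scores
    if not result.adjusted:
        scores = pd.Series(bh_adjust(scores.to_numpy()), index=scores.index)
    called: Set[str] = set()
    for feature_id, q in scores.items():
        if q > alpha:
            continue
        b = bins_by_id[feature_id]
        if b.is_transcript_specific:
            called.add(next(iter(b.member_transcripts)))
    return CallSet(called, alpha=alpha, provenance=result.provenance)


def evaluate_calls(calls: CallSet, truth: TruthTable) -> EvaluationResult:
    """TP/FP, detection percentage and realized FDR against the truth."""
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    truth_ids = truth.transcript_ids
    tp = len(calls.called_transcripts & truth_ids)
    fp = len(calls.called_transcripts - truth_ids)
    return EvaluationResult(
        tp=tp,
        fp=fp,
        n_truth=len(truth_ids),
        detection_pct=100.0 * tp / len(truth_ids),
        realized_fdr=fp / max(tp + fp, 1),
    )


def ma_statistics(counts: CountsMatrix, epsilon: float = 0.5) -> pd.DataFrame:
    """Per-feature MA statistics for an MA plot of the benchmark.

    For each feature: ``avg_log2fc`` = log2((mean T + eps) / (mean C + eps))
    and ``avg_log10_count`` = log10(mean over the union of all samples +
    eps); the pseudocount eps keeps zero-count features finite.
    """
    c_samples = counts.samples_in_group("C")
    t_samples = counts.samples_in_group("T")
    if not c_samples or not t_samples:
        raise ValueError("both C and T groups must be present")
    mean_c = counts.values[c_samples].mean(axis=1)
    mean_t = counts.values[t_samples].mean(axis=1)
    mean_all = counts.values.mean(axis=1)
    return pd.DataFrame(
        {
            "avg_log2fc": np.log2((mean_t + epsilon) / (mean_c + epsilon)),
            "avg_log10_count": np.log10(mean_all + epsilon),
        },
        index=counts.values.index,
    )


def two_group_count_test(
    counts: pd.DataFrame,
    group_of: Mapping[str, str],
    provenance: str = "welch-log",
) -> CallerResult:
    """Simple built-in two-group test on a features x samples count table.

    Welch's t-test on log2(count + 1) per feature, BH-adjusted across all
    features; returns a transcript-level CallerResult whose scores behave
    like q-values.  This is the reference caller used for end-to-end smoke
    runs — benchmark users normally feed their own caller's table instead.
    """
    c_samples = [s for s in counts.columns if group_of[s] == "C"]
    t_samples = [s for s in counts.columns if group_of[s] == "T"]
    if not c_samples or not t_samples:
        raise ValueError("both C and T groups must be present")
    logged = np.log2(counts.to_numpy(dtype=float) + 1.0)
    idx_c = [counts.columns.get_loc(s) for s in c_samples]
    idx_t = [counts.columns.get_loc(s) for s in t_samples]
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trigger scipy precision warnings; they map to p=1
        warnings.simplefilter("ignore", RuntimeWarning)
        _, pvals = stats.ttest_ind(
            logged[:, idx_t], logged[:, idx_c], axis=1, equal_var=False
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    qvals = bh_adjust(pvals)
    return CallerResult(
        level="transcript",
        scores=pd.Series(qvals, index=counts.index),
        adjusted=True,
        provenance=provenance,
    )
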