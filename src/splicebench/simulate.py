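"""Spike-in read simulation and injection.

Synthetic spike reads are 2x51 nt paired-end fragments tiled deterministically
over the spliced transcript so that coverage is uniform at both exon and
exon-exon junction level; every base is written with a fixed Phred quality
of 40.  The number of reads injected per replicate is drawn from a seeded
population of 10^5 values ~ Normal(mean, mean/10), rounded and clipped at
zero, mimicking replicate-to-replicate count noise in a biological group.
Reads can alternatively be extracted from an indexed alignment over the
target transcript's exons.  Injection appends spike records to background
FASTQs and emits a machine-readable truth table.
"""

from __future__ import annotations

import gzip
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import TranscriptModel, reverse_complement

logger = logging.getLogger(__name__)

GROUPS = ("C", "T")


@dataclass(frozen=True)
class SpikeEntry:
    transcript_id: str
    group: str
    mean_reads: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.mean_reads < 0:
            raise ValueError("mean_reads must be >= 0")


@dataclass
class SpikePlan:
    """Which transcripts to spike where, and the read-construction geometry.

    A transcript may carry one entry per group with different means to
    encode a finite expected fold change; duplicate (transcript, group)
    pairs are rejected.  Replicate count noise follows sd = mean / 10.
    """

    entries: List[SpikeEntry] = field(default_factory=list)
    read_length: int = 51
    fragment_length: int = 150
    base_quality: int = 40
    population_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_length:
            raise ValueError("read_length must not exceed fragment_length")
        if self.read_length < 1 or self.population_size < 1:
            raise ValueError("read_length and population_size must be positive")
        if not 0 <= self.base_quality <= 93:
            raise ValueError("base_quality must be a printable Phred+33 score")
        seen = set()
        for e in self.entries:
            key = (e.transcript_id, e.group)
            if key in seen:
                raise ValueError(f"duplicate spike entry for {key}")
            seen.add(key)

    @staticmethod
    def sd_for_mean(mean: float) -> float:
        return mean / 10.0

    def entries_for(self, group: str) -> List[SpikeEntry]:
        return [e for e in self.entries if e.group == group]

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write(
                f"# read_length={self.read_length} "
                f"fragment_length={self.fragment_length} "
                f"base_quality={self.base_quality} "
                f"population_size={self.population_size} seed={self.seed}\n"
            )
            out.write("transcript_id\tgroup\tmean_reads\n")
            for e in self.entries:
                out.write(f"{e.transcript_id}\t{e.group}\t{e.mean_reads}\n")

    @classmethod
    def from_tsv(cls, path, **overrides) -> "SpikePlan":
        params: Dict[str, int] = {}
        entries: List[SpikeEntry] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for token in line.lstrip("# ").split():
                        key, _, value = token.partition("=")
                        if key in {
                            "read_length",
                            "fragment_length",
                            "base_quality",
                            "population_size",
                            "seed",
                        }:
                            params[key] = int(value)
                    continue
                if not line or line.startswith("transcript_id"):
                    continue
                tid, group, mean = line.split("\t")
                entries.append(SpikeEntry(tid, group, int(mean)))
        params.update(overrides)
        return cls(entries=entries, **params)


@dataclass(frozen=True)
class ReadPair:
    """One sequenced fragment: mate1 is the fragment 5' end, mate2 the
    reverse complement of its 3' end (FR orientation)."""

    fragment_start: int
    mate1_seq: str
    mate2_seq: str
    origin_transcript: str


def count_population(mean: float, plan: SpikePlan, rng: np.random.Generator) -> np.ndarray:
    """The full replicate-count sampling population for one spike mean.

    ``population_size`` draws from Normal(mean, mean/10), rounded half-up to
    integers and clipped at zero.  Replicate counts are sampled from this
    population rather than from the continuous distribution directly.
    """
    if mean < 0:
        raise ValueError("mean must be >= 0")
    pop = rng.normal(loc=mean, scale=SpikePlan.sd_for_mean(mean), size=plan.population_size)
    return np.clip(np.floor(pop + 0.5), 0, None).astype(np.int64)


def sample_replicate_counts(
    mean: int,
    n_replicates: int,
    plan: SpikePlan,
    rng: Optional[np.random.Generator] = None,
) -> List[int]:
    """Per-replicate spike counts for one transcript in one group."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    pop = count_population(mean, plan, rng)
    draw = rng.choice(pop, size=n_replicates, replace=False)
    return [int(v) for v in draw]


def _admissible_starts(spliced_length: int, fragment_length: int) -> int:
    return spliced_length - fragment_length + 1


def tile_starts(spliced_length: int, fragment_length: int, n_fragments: int) -> List[int]:
    """Deterministic fragment starts giving uniform coverage.

    Full passes use every admissible start once; a final partial pass of k
    fragments spreads them evenly (floor(j * n_starts / k)), so every start
    is used before any is reused and coverage stays as even as possible.
    """
    n_starts = _admissible_starts(spliced_length, fragment_length)
    full, rem = divmod(n_fragments, n_starts)
    starts: List[int] = []
    for _ in range(full):
        starts.extend(range(n_starts))
    if rem:
        starts.extend(math.floor(j * n_starts / rem) for j in range(rem))
    return starts


def _pair_from_start(seq: str, start: int, plan: SpikePlan, origin: str) -> ReadPair:
    frag = seq[start : start + plan.fragment_length]
    return ReadPair(
        fragment_start=start,
        mate1_seq=frag[: plan.read_length],
        mate2_seq=reverse_complement(frag[-plan.read_length :]),
        origin_transcript=origin,
    )


def tile_reads(
    transcript: TranscriptModel,
    sequence: str,
    n_fragments: int,
    plan: SpikePlan,
) -> List[ReadPair]:
    """Uniform-coverage paired reads over one spliced transcript."""
    sequence = sequence.upper()
    if len(sequence) != transcript.spliced_length:
        raise ValueError(
            f"{transcript.transcript_id}: sequence length {len(sequence)} != "
            f"spliced_length {transcript.spliced_length}"
        )
    if transcript.spliced_length < plan.fragment_length:
        raise ValueError(
            f"{transcript.transcript_id}: spliced length "
            f"{transcript.spliced_length} < fragment length {plan.fragment_length}"
        )
    starts = tile_starts(transcript.spliced_length, plan.fragment_length, n_fragments)
    return [
        _pair_from_start(sequence, s, plan, transcript.transcript_id) for s in starts
    ]


def random_reads(
    transcript: TranscriptModel,
    sequence: str,
    n_fragments: int,
    plan: SpikePlan,
    rng: np.random.Generator,
) -> List[ReadPair]:
    """Reads with uniformly random (seeded) fragment starts; used for
    alignment-realistic background reads rather than spikes."""
    sequence = sequence.upper()
    if transcript.spliced_length < plan.fragment_length:
        raise ValueError(
            f"{transcript.transcript_id}: spliced length "
            f"{transcript.spliced_length} < fragment length {plan.fragment_length}"
        )
    n_starts = _admissible_starts(transcript.spliced_length, plan.fragment_length)
    starts = rng.integers(0, n_starts, size=n_fragments)
    return [
        _pair_from_start(sequence, int(s), plan, transcript.transcript_id)
        for s in starts
    ]


def _open_text(path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def emit_fastq(
    pairs: Sequence[ReadPair],
    plan: SpikePlan,
    out1,
    out2,
    prefix: str = "spike",
    anonymize: bool = False,
    append: bool = False,
) -> int:
    """Write paired FASTQ files (Phred+33, constant quality, matched order).

    Read ids embed the origin transcript (``prefix|transcript|serial``)
    unless ``anonymize`` strips the truth down to ``prefix|serial``.
    Returns the number of pairs written.
    """
    qual = chr(plan.base_quality + 33)
    mode = "a" if append else "w"
    seen_ids = set()
    with _open_text(out1, mode) as f1, _open_text(out2, mode) as f2:
        for serial, pair in enumerate(pairs):
            if anonymize:
                rid = f"{prefix}|{serial}"
            else:
                rid = f"{prefix}|{pair.origin_transcript}|{serial}"
            if rid in seen_ids:
                raise ValueError(f"duplicate read id {rid!r}")
            seen_ids.add(rid)
            f1.write(f"@{rid}\n{pair.mate1_seq}\n+\n{qual * len(pair.mate1_seq)}\n")
            f2.write(f"@{rid}\n{pair.mate2_seq}\n+\n{qual * len(pair.mate2_seq)}\n")
    return len(pairs)


def count_fastq_records(path) -> int:
    n_lines = 0
    with _open_text(path, "r") as fh:
        for _ in fh:
            n_lines += 1
    if n_lines % 4:
        raise ValueError(f"{path}: truncated FASTQ ({n_lines} lines)")
    return n_lines // 4


def tally_origins(path) -> Dict[str, int]:
    """Count FASTQ records per origin transcript from structured read ids.

    Ids written by this package look like ``prefix|transcript|serial``;
    anything else is tallied under ``"unknown"``.
    """
    tally: Dict[str, int] = {}
    with _open_text(path, "r") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 0:
                parts = line[1:].rstrip("\n").split("|")
                origin = parts[1] if len(parts) == 3 else "unknown"
                tally[origin] = tally.get(origin, 0) + 1
    return tally


@dataclass(frozen=True)
class ExtractedPair:
    name: str
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str


def _original_orientation(read) -> Tuple[str, str]:
    """Sequence/quality as sequenced (undo alignment reverse-complementing)."""
    seq = read.query_sequence or ""
    qual = "".join(chr(q + 33) for q in (read.query_qualities or []))
    if read.is_reverse:
        seq = reverse_complement(seq)
        qual = qual[::-1]
    return seq, qual


def extract_mapped_spikes(
    bam_path,
    transcript: TranscriptModel,
    n_needed: int,
    seed: int,
) -> List[ExtractedPair]:
    """Extract read pairs overlapping a transcript's exons from an indexed BAM.

    A pair qualifies when at least one mate overlaps at least one exon;
    pairs are kept intact (both mates or neither).  Unpaired or
    mate-missing alignments are skipped with a logged count.  When more
    pairs qualify than needed, a seeded subsample is returned.
    """
    import pysam

    with pysam.AlignmentFile(str(bam_path), "rb") as af:
        try:
            af.check_index()
        except ValueError as exc:
            raise OSError(f"{bam_path}: missing BAM index") from exc
        wanted = set()
        for start, end in transcript.exons:
            for read in af.fetch(transcript.chrom, start, end):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                wanted.add(read.query_name)
        mates: Dict[str, Dict[int, object]] = {}
        n_skipped_unpaired = 0
        for read in af.fetch():
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.query_name not in wanted:
                continue
            if not read.is_paired:
                n_skipped_unpaired += 1
                continue
            mates.setdefault(read.query_name, {})[1 if read.is_read1 else 2] = read

    complete = sorted(name for name, d in mates.items() if len(d) == 2)
    n_incomplete = len(mates) - len(complete)
    if n_skipped_unpaired or n_incomplete:
        logger.warning(
            "extract_mapped_spikes(%s): skipped %d unpaired alignments, "
            "%d pairs with a missing mate",
            transcript.transcript_id,
            n_skipped_unpaired,
            n_incomplete,
        )
    if len(complete) > n_needed:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(complete), size=n_needed, replace=False)
        complete = [complete[i] for i in sorted(idx)]
    out = []
    for name in complete:
        s1, q1 = _original_orientation(mates[name][1])
        s2, q2 = _original_orientation(mates[name][2])
        out.append(ExtractedPair(name, s1, q1, s2, q2))
    return out


def extracted_to_fastq(records: Sequence[ExtractedPair], out1, out2) -> int:
    with _open_text(out1, "w") as f1, _open_text(out2, "w") as f2:
        for r in records:
            f1.write(f"@{r.name}\n{r.mate1_seq}\n+\n{r.mate1_qual}\n")
            f2.write(f"@{r.name}\n{r.mate2_seq}\n+\n{r.mate2_qual}\n")
    return len(records)


class TruthTable:
    """Per-transcript injected counts, target group(s) and expected log2 FC.

    ``expected_log2fc`` is log2(mean injected T counts / mean injected C
    counts), finite only when both group means are positive; otherwise the
    transcript is flagged ``exclusive_presence``.
    """

    COUNT_PREFIX = "n_"

    def __init__(self, frame: pd.DataFrame):
        counts = frame[[c for c in frame.columns if c.startswith(self.COUNT_PREFIX)]]
        if counts.size and (counts.to_numpy() < 0).any():
            raise ValueError("injected counts must be >= 0")
        self.frame = frame

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        group_of: Mapping[str, str],
    ) -> "TruthTable":
        """Build from a transcripts x samples table of injected read counts."""
        c_samples = [s for s in counts.columns if group_of[s] == "C"]
        t_samples = [s for s in counts.columns if group_of[s] == "T"]
        rows = []
        for tid, row in counts.iterrows():
            mean_c = float(row[c_samples].mean()) if c_samples else 0.0
            mean_t = float(row[t_samples].mean()) if t_samples else 0.0
            groups = ("C" if mean_c > 0 else "") + ("T" if mean_t > 0 else "")
            exclusive = not (mean_c > 0 and mean_t > 0)
            lfc = math.log2(mean_t / mean_c) if not exclusive else math.nan
            rec = {"transcript_id": tid, "group": groups or "none"}
            rec.update({f"{cls.COUNT_PREFIX}{s}": int(row[s]) for s in counts.columns})
            rec["expected_log2fc"] = lfc
            rec["exclusive_presence"] = exclusive
            rows.append(rec)
        frame = pd.DataFrame(rows).set_index("transcript_id") if rows else pd.DataFrame(
            columns=["group", "expected_log2fc", "exclusive_presence"]
        ).rename_axis("transcript_id")
        return cls(frame)

    @property
    def transcript_ids(self) -> set:
        return set(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def build_spike_fastqs(
    plan: SpikePlan,
    transcripts: Mapping[str, TranscriptModel],
    sequences: Mapping[str, str],
    samples_by_group: Mapping[str, Sequence[str]],
    out_dir,
    anonymize: bool = False,
) -> Tuple[Dict[str, Tuple[str, str]], pd.DataFrame]:
    """Generate per-sample spike FASTQ pairs for a whole plan.

    Returns (sample -> (mate1 path, mate2 path), transcripts x samples
    table of injected pair counts).  Fully deterministic under plan.seed:
    each entry draws from an rng keyed by (plan.seed, entry index).
    """
    os.makedirs(out_dir, exist_ok=True)
    all_samples = [s for g in GROUPS for s in samples_by_group.get(g, [])]
    counts = pd.DataFrame(
        0,
        index=sorted({e.transcript_id for e in plan.entries}),
        columns=all_samples,
        dtype=np.int64,
    )
    pairs_per_sample: Dict[str, List[ReadPair]] = {s: [] for s in all_samples}
    for i, entry in enumerate(plan.entries):
        rng = np.random.default_rng([plan.seed, i])
        samples = list(samples_by_group.get(entry.group, []))
        reps = sample_replicate_counts(entry.mean_reads, len(samples), plan, rng)
        tx = transcripts[entry.transcript_id]
        seq = sequences[entry.transcript_id]
        for sample, n in zip(samples, reps):
            pairs_per_sample[sample].extend(tile_reads(tx, seq, n, plan))
            counts.loc[entry.transcript_id, sample] += n
    paths: Dict[str, Tuple[str, str]] = {}
    for sample in all_samples:
        p1 = os.path.join(out_dir, f"{sample}_spikes_R1.fastq")
        p2 = os.path.join(out_dir, f"{sample}_spikes_R2.fastq")
        emit_fastq(pairs_per_sample[sample], plan, p1, p2, anonymize=anonymize)
        paths[sample] = (p1, p2)
    return paths, counts


def inject_spikes(
    background_fastqs: Mapping[str, Tuple[str, str]],
    spike_fastqs: Mapping[str, Tuple[str, str]],
    out_dir,
    group_of: Mapping[str, str],
    spike_counts: Optional[pd.DataFrame] = None,
) -> TruthTable:
    """Append spike records to background FASTQs, sample by sample.

    Each output sample FASTQ is the background records followed by the
    spike records, mate files kept in matching order; record counts add
    exactly.  The truth table is built from ``spike_counts`` (transcripts x
    samples) when given, else by tallying origin transcripts from the spike
    read ids (which fails to attribute anonymized ids).
    """
    unknown = set(spike_fastqs) - set(background_fastqs)
    if unknown:
        raise ValueError(f"spike samples not present in background: {sorted(unknown)}")
    os.makedirs(out_dir, exist_ok=True)
    tallies: Dict[str, Dict[str, int]] = {}
    for sample, (bg1, bg2) in background_fastqs.items():
        n_bg1, n_bg2 = count_fastq_records(bg1), count_fastq_records(bg2)
        if n_bg1 != n_bg2:
            raise ValueError(
                f"{sample}: background mate counts differ ({n_bg1} vs {n_bg2})"
            )
        sp = spike_fastqs.get(sample)
        if sp is not None:
            n_sp1, n_sp2 = count_fastq_records(sp[0]), count_fastq_records(sp[1])
            if n_sp1 != n_sp2:
                raise ValueError(
                    f"{sample}: spike mate counts differ ({n_sp1} vs {n_sp2})"
                )
        out1 = os.path.join(out_dir, f"{sample}_R1.fastq")
        out2 = os.path.join(out_dir, f"{sample}_R2.fastq")
        for mate, out in ((0, out1), (1, out2)):
            with _open_text(out, "w") as dst:
                with _open_text((bg1, bg2)[mate], "r") as src:
                    for line in src:
                        dst.write(line)
                if sp is not None:
                    with _open_text(sp[mate], "r") as src:
                        for line in src:
                            dst.write(line)
        if spike_counts is None and sp is not None:
            tallies[sample] = tally_origins(sp[0])

    if spike_counts is None:
        transcripts = sorted({t for d in tallies.values() for t in d})
        spike_counts = pd.DataFrame(
            {s: [tallies.get(s, {}).get(t, 0) for t in transcripts]
             for s in background_fastqs},
            index=transcripts,
            dtype=np.int64,
        )
    else:
        spike_counts = spike_counts.reindex(
            columns=list(background_fastqs), fill_value=0
        )
    return TruthTable.from_counts(spike_counts, group_of)
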