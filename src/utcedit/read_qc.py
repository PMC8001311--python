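"""Read-level quality control defining "clean reads".

A raw read is discarded when any of three rules fires, checked in this
order:

1. adapter contamination — the configured adapter occurs as an exact
   substring of the read;
2. N content — uncertain bases (``N``) make up *more than* ``n_fraction_max``
   of the read (strict inequality, default 10%);
3. low quality — bases below ``lowq_threshold`` (default Q20) make up
   *more than* ``lowq_fraction_max`` of the read (strict, default 50%).

Both fraction thresholds are strict ``>`` comparisons: a 100-base read with
exactly 10 Ns or exactly 50 sub-Q20 bases is kept.  In paired-end mode a
pair is discarded whenever either mate fails.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "QcParams",
    "FilterDecision",
    "QcSummary",
    "filter_read",
    "filter_pair",
    "qc_summary",
    "qc_summary_paired",
    "read_fastq",
    "write_fastq",
    "filter_fastq",
]

#: Illumina TruSeq/NEBNext ligated-adaptor stem.
DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class Read:
    """A sequencing read: id, base string over {A,C,G,T,N}, Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QcParams:
    """Thresholds for the three clean-read rules."""

    adapter_sequence: str = DEFAULT_ADAPTER
    n_fraction_max: float = 0.10
    lowq_threshold: int = 20
    lowq_fraction_max: float = 0.50

    def __post_init__(self):
        for name in ("n_fraction_max", "lowq_fraction_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None  # "empty" | "adapter" | "n-fraction" | "low-quality"


@dataclass
class QcSummary:
    """Kept/discarded tallies; ``kept + sum(discarded) == total``."""

    total: int = 0
    kept: int = 0
    discarded: Counter = field(default_factory=Counter)

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [("total", self.total), ("kept", self.kept)]
        for reason in ("empty", "adapter", "n-fraction", "low-quality"):
            rows.append((f"discarded:{reason}", self.discarded.get(reason, 0)))
        return rows


def filter_read(read: Read, params: QcParams) -> FilterDecision:
    """Apply the clean-read rules; the reason names the first rule that fired."""
    n = len(read)
    if n == 0:
        return FilterDecision(False, "empty")
    if params.adapter_sequence and params.adapter_sequence in read.sequence:
        return FilterDecision(False, "adapter")
    if read.sequence.count("N") / n > params.n_fraction_max:
        return FilterDecision(False, "n-fraction")
    lowq = sum(1 for q in read.qualities if q < params.lowq_threshold)
    if lowq / n > params.lowq_fraction_max:
        return FilterDecision(False, "low-quality")
    return FilterDecision(True, None)


def filter_pair(read1: Read, read2: Read, params: QcParams) -> FilterDecision:
    """Paired mode: both mates are discarded if either fails."""
    d1 = filter_read(read1, params)
    if not d1.keep:
        return d1
    return filter_read(read2, params)


def qc_summary(reads: Iterable[Read], params: QcParams) -> QcSummary:
    summary = QcSummary()
    for read in reads:
        summary.total += 1
        decision = filter_read(read, params)
        if decision.keep:
            summary.kept += 1
        else:
            summary.discarded[decision.reason] += 1
    return summary


def qc_summary_paired(
    pairs: Iterable[tuple[Read, Read]], params: QcParams
) -> QcSummary:
    """Per-read tallies where a failing mate drags down its partner."""
    summary = QcSummary()
    for r1, r2 in pairs:
        summary.total += 2
        decision = filter_pair(r1, r2, params)
        if decision.keep:
            summary.kept += 2
        else:
            summary.discarded[decision.reason] += 2
    return summary


def read_fastq(path) -> Iterator[Read]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
        )


def write_fastq(reads: Iterable[Read], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = list(read.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def filter_fastq(
    in_path, out_path, params: QcParams
) -> tuple[QcSummary, Sequence[Read]]:
    """Filter a FASTQ file to clean reads; returns the summary and kept reads."""
    summary = QcSummary()
    kept: list[Read] = []
    for read in read_fastq(in_path):
        summary.total += 1
        decision = filter_read(read, params)
        if decision.keep:
            summary.kept += 1
            kept.append(read)
        else:
            summary.discarded[decision.reason] += 1
    write_fastq(kept, out_path)
    return summary, kept
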