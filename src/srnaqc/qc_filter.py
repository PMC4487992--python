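"""Read-level QC: adapter trimming, dimer detection and the four read filters.

A 50 nt single-end small RNA read is the biological insert followed by the
TruSeq small RNA 3' adapter and arbitrary read-through content. Each raw read
lands in exactly one of five mutually exclusive categories:

``dimer``
    The adapter seed starts at position 0 — an adapter-adapter ligation
    product with no biological insert.
``too_short``
    Insert shorter than ``min_len`` (default 15 nt): degraded-RNA fragments.
``long_rna``
    No adapter seed detected anywhere in the read, or an insert longer than
    ``max_len`` (default 40 nt): mid-size and larger ncRNA populations. With
    50 nt reads and a perfect 10 nt adapter seed the two descriptions
    coincide — any insert > 40 nt leaves fewer than 10 adapter bases.
``low_quality``
    Mean Phred score of the trimmed insert below ``min_mean_q`` (default 30).
``surviving``
    Everything else; the insert (read up to the adapter) is emitted.

Filter precedence is adapter-detection → dimer → size → quality so that every
read has exactly one category. Boundary semantics: inserts of exactly
``min_len`` and exactly ``max_len`` nt survive, as does a mean quality of
exactly ``min_mean_q`` (reads *below* the cutoffs are removed).

The quality *filter* is evaluated on the trimmed insert (the biologically
relevant bases); the reported per-library "average quality" is the mean over
whole raw reads, matching how per-library quality is usually summarized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import QCReport, Read

#: Illumina TruSeq small RNA 3' adapter.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Mutually exclusive read categories, in reporting order.
CATEGORIES = ("dimer", "too_short", "low_quality", "long_rna", "surviving")


@dataclass(frozen=True)
class QCParams:
    """Parameters of the four read filters.

    Defaults are the standard small RNA pipeline settings: perfect 10 nt
    adapter-seed match, 15–40 nt insert window, mean Phred >= 30.
    """

    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    adapter_seed_len: int = 10
    min_len: int = 15
    max_len: int = 40
    min_mean_q: float = 30.0

    def __post_init__(self) -> None:
        if self.adapter_seed_len < 1:
            raise ValueError("adapter_seed_len must be >= 1")
        if len(self.adapter) < self.adapter_seed_len:
            raise ValueError("adapter shorter than adapter_seed_len")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")


@dataclass
class TrimmedRead:
    """Outcome of classifying one read: its category and (if surviving) the
    trimmed insert with its qualities."""

    category: str
    insert: str = ""
    insert_quals: np.ndarray | None = None


def phred_error_prob(q: float | np.ndarray) -> float | np.ndarray:
    """Per-base sequencing error probability for Phred score ``q``.

    ``10 ** (-q / 10)``; e.g. Q=10 -> 0.1 (90 % base-call accuracy),
    Q=30 -> 0.001 (99.9 %).
    """
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("Phred scores must be non-negative")
    result = 10.0 ** (-q / 10.0)
    return float(result) if result.ndim == 0 else result


def mean_quality(quals: Sequence[int] | np.ndarray) -> float:
    """Arithmetic mean of integer Phred scores; errors on an empty list."""
    arr = np.asarray(quals)
    if arr.size == 0:
        raise ValueError("mean quality of an empty score list is undefined")
    return float(arr.mean())


def find_adapter(seq: str, adapter: str, seed_len: int = 10) -> int | None:
    """0-based position of the leftmost exact match of ``adapter[:seed_len]``
    in ``seq``, or ``None`` if the seed does not occur."""
    if seed_len < 1:
        raise ValueError("seed_len must be >= 1")
    if len(adapter) < seed_len:
        raise ValueError("adapter shorter than seed_len")
    pos = seq.find(adapter[:seed_len])
    return None if pos < 0 else pos


def classify_read(read: Read, params: QCParams = QCParams()) -> TrimmedRead:
    """Assign one read to exactly one QC category (see module docstring)."""
    pos = find_adapter(read.seq, params.adapter, params.adapter_seed_len)
    if pos is None:
        return TrimmedRead("long_rna")
    if pos == 0:
        return TrimmedRead("dimer")
    if pos < params.min_len:
        return TrimmedRead("too_short")
    if pos > params.max_len:
        return TrimmedRead("long_rna")
    insert_quals = read.quals[:pos]
    if mean_quality(insert_quals) < params.min_mean_q:
        return TrimmedRead("low_quality")
    return TrimmedRead("surviving", insert=read.seq[:pos], insert_quals=insert_quals)


def run_qc(
    reads: Iterable[Read],
    params: QCParams = QCParams(),
    library_id: str = "",
) -> tuple[list[Read], QCReport]:
    """Filter and trim a library, returning surviving inserts and a QCReport.

    Every input read lands in exactly one category, so category counts sum to
    the raw read total. Surviving reads keep their ids and input order, with
    ``seq``/``quals`` replaced by the trimmed insert. The report's category
    percentages are taken over raw reads and its ``mean_quality`` is the mean
    of per-read mean Phred scores over all raw reads. An empty input yields a
    report with ``raw_reads == 0`` and percentages defined as zero.
    """
    report = QCReport(library_id=library_id)
    survivors: list[Read] = []
    qual_sum = 0.0
    for read in reads:
        report.raw_reads += 1
        if len(read.quals):
            qual_sum += float(np.mean(read.quals))
        trimmed = classify_read(read, params)
        if trimmed.category == "surviving":
            report.n_surviving += 1
            survivors.append(
                Read(id=read.id, seq=trimmed.insert, quals=trimmed.insert_quals)
            )
        elif trimmed.category == "dimer":
            report.n_dimer += 1
        elif trimmed.category == "too_short":
            report.n_too_short += 1
        elif trimmed.category == "low_quality":
            report.n_low_quality += 1
        else:
            report.n_long_rna += 1
    if report.raw_reads:
        report.mean_quality = qual_sum / report.raw_reads
    return survivors, report
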