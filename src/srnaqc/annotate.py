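"""Map surviving inserts to a classed reference set and account for them.

This replaces genome alignment + database annotation with direct matching
against classed reference sequences: a k-mer index proposes candidate
features, and each candidate is verified by Hamming distance, either at equal
length or — in containment mode, the default — at every offset where the
insert fits inside the reference (mature miRNAs are substrings of their
hairpins). Matching is exact in the sense that the hit set always equals an
exhaustive Hamming scan over the whole reference set:

* ``max_mismatches == 0``: any k-mer of a matching insert occurs verbatim in
  the reference, so k-mer candidate generation is complete.
* ``max_mismatches >= 1``: a single mismatch can break at most ``k``
  consecutive k-mer windows, so candidate generation from all windows is
  complete whenever ``len(insert) - k + 1 > k * max_mismatches``. Below that
  length the aligner falls back to scanning every reference sequence
  (early-abort Hamming), which at reference-set scale is cheap — and
  :func:`annotate_library` deduplicates inserts before aligning, so each
  distinct insert is verified once no matter how deep the library is.

Each mapped read is assigned one class by a fixed priority hierarchy
(miRNA > other ncRNA > repeat > coding > unannotated), evaluated among the
minimum-mismatch hits, mirroring pipelines that consult miRBase before Rfam
and repeat databases. Reads whose best hits all share one feature — or, for
miRNAs, one mature name — count as uniquely mapped; everything else mapped is
multi-mapped. A multi-mapped read contributes one full count to its collapsed
mature name when all best hits agree, otherwise 1/n to each tied name, so no
read is ever counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import QCReport, Read, ReferenceDB

#: Annotation class priority (lower = assigned first among tied hits).
CLASS_PRIORITY = {
    "miRNA": 0,
    "other_ncRNA": 1,
    "repeat": 2,
    "coding": 3,
    "unannotated": 4,
}


@dataclass(frozen=True)
class Hit:
    """One insert-to-feature match within the mismatch budget."""

    feature_id: str
    rna_class: str
    mature_name: str
    n_mismatches: int


@dataclass(frozen=True)
class AnnotationCall:
    """Mapping status and class assigned to one insert.

    status ∈ {unmapped, unique, multi}; ``rna_class`` is ``None`` for
    unmapped inserts; ``mature_name`` is set for miRNA calls whose best hits
    collapse to a single mature sequence.
    """

    status: str
    rna_class: str | None = None
    mature_name: str | None = None


class RefIndex:
    """k-mer lookup over a ReferenceDB plus the per-run matching mode."""

    def __init__(
        self,
        db: ReferenceDB,
        k: int = 10,
        max_mismatches: int = 1,
        containment: bool = True,
    ):
        if k < 10:
            raise ValueError("k must be >= 10")
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        offenders = [rec.feature_id for rec in db if len(rec.seq) < k]
        if offenders:
            raise ValueError(
                f"reference sequences shorter than k={k}: {offenders}"
            )
        self.k = k
        self.max_mismatches = max_mismatches
        self.containment = containment
        self.records = {rec.feature_id: rec for rec in db}
        self.kmers: dict[str, set[str]] = {}
        for rec in db:
            seq = rec.seq
            for i in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[i : i + k], set()).add(rec.feature_id)

    def __len__(self) -> int:
        return len(self.records)


def build_index(
    db: ReferenceDB,
    k: int = 10,
    max_mismatches: int = 1,
    containment: bool = True,
) -> RefIndex:
    """Build a deterministic k-mer index; every reference sequence is
    findable by exact self-query."""
    return RefIndex(db, k=k, max_mismatches=max_mismatches, containment=containment)


def _best_hamming(insert: str, ref_seq: str, max_mm: int, containment: bool) -> int:
    """Minimum Hamming distance of ``insert`` against ``ref_seq`` over all
    admissible offsets, or -1 if it exceeds ``max_mm`` everywhere."""
    L, R = len(insert), len(ref_seq)
    if containment:
        if R < L:
            return -1
        offsets = range(R - L + 1)
    else:
        if R != L:
            return -1
        offsets = range(1)
    best = -1
    limit = max_mm
    for off in offsets:
        mm = 0
        window = ref_seq[off : off + L]
        for a, b in zip(insert, window):
            if a != b:
                mm += 1
                if mm > limit:
                    break
        else:
            if best == -1 or mm < best:
                best = mm
                if best == 0:
                    return 0
            limit = best  # only look for strictly better offsets
    return best


def align_insert(insert: str, index: RefIndex) -> list[Hit]:
    """All features matching ``insert`` within the index's mismatch budget,
    sorted by (n_mismatches, feature_id). Empty list = unmapped."""
    L, k = len(insert), index.k
    if L < k:
        return []
    complete = index.max_mismatches == 0 or (L - k + 1) > k * index.max_mismatches
    if complete:
        candidates: set[str] = set()
        for i in range(L - k + 1):
            candidates |= index.kmers.get(insert[i : i + k], set())
    else:
        candidates = set(index.records)
    hits = []
    for fid in candidates:
        rec = index.records[fid]
        mm = _best_hamming(insert, rec.seq, index.max_mismatches, index.containment)
        if mm >= 0:
            hits.append(Hit(fid, rec.rna_class, rec.mature_name, mm))
    hits.sort(key=lambda h: (h.n_mismatches, h.feature_id))
    return hits


def assign_annotation(hits: list[Hit]) -> AnnotationCall:
    """Collapse a hit list into one mapping status and one class.

    Only the minimum-mismatch stratum is considered. Class = highest-priority
    class among those hits. Status is ``unique`` when the stratum names one
    feature, or — for miRNA calls — one mature name; otherwise ``multi``.
    """
    if not hits:
        return AnnotationCall(status="unmapped")
    best_mm = hits[0].n_mismatches
    best = [h for h in hits if h.n_mismatches == best_mm]
    rna_class = min(best, key=lambda h: CLASS_PRIORITY[h.rna_class]).rna_class
    feature_ids = {h.feature_id for h in best}
    mature_name: str | None = None
    if rna_class == "miRNA":
        mature_names = {h.mature_name for h in best}
        if len(mature_names) == 1:
            mature_name = next(iter(mature_names))
            status = "unique"
        elif len(feature_ids) == 1:
            status = "unique"
        else:
            status = "multi"
    else:
        status = "unique" if len(feature_ids) == 1 else "multi"
    return AnnotationCall(status=status, rna_class=rna_class, mature_name=mature_name)


@dataclass
class AnnotationResult:
    """Accounting of one library's surviving reads against the reference."""

    n_surviving: int = 0
    n_unmapped: int = 0
    n_unique: int = 0
    n_multi: int = 0
    class_read_counts: dict[str, int] = field(default_factory=dict)
    #: mature-name level miRNA counts (fractional when best hits tie across
    #: mature names)
    mirna_counts: dict[str, float] = field(default_factory=dict)
    #: feature-level counts for the non-miRNA classes
    other_counts: dict[str, float] = field(default_factory=dict)
    feature_classes: dict[str, str] = field(default_factory=dict)

    def all_counts(self) -> dict[str, float]:
        """Combined feature space: mature miRNA names plus other features."""
        merged = dict(self.mirna_counts)
        merged.update(self.other_counts)
        return merged

    def mirna_detected(self, threshold: float) -> int:
        return sum(1 for v in self.mirna_counts.values() if v >= threshold)


def annotate_library(
    survivors: Iterable[Read | str], index: RefIndex
) -> AnnotationResult:
    """Annotate the surviving reads of one library.

    Each read contributes exactly 1 to one of {unmapped, unique, multi} and,
    if mapped, exactly 1 to one class and (fractionally, if tied) to the
    features/mature names of its best stratum. Inserts are deduplicated so
    each distinct sequence is aligned once.
    """
    result = AnnotationResult()
    insert_tally: dict[str, int] = {}
    for read in survivors:
        seq = read if isinstance(read, str) else read.seq
        insert_tally[seq] = insert_tally.get(seq, 0) + 1
        result.n_surviving += 1

    for seq, n in insert_tally.items():
        hits = align_insert(seq, index)
        call = assign_annotation(hits)
        if call.status == "unmapped":
            result.n_unmapped += n
            continue
        if call.status == "unique":
            result.n_unique += n
        else:
            result.n_multi += n
        cls = call.rna_class
        result.class_read_counts[cls] = result.class_read_counts.get(cls, 0) + n
        best_mm = hits[0].n_mismatches
        best = [h for h in hits if h.n_mismatches == best_mm and h.rna_class == cls]
        if cls == "miRNA":
            names = sorted({h.mature_name for h in best})
            share = n / len(names)
            for name in names:
                result.mirna_counts[name] = result.mirna_counts.get(name, 0.0) + share
                result.feature_classes[name] = "miRNA"
        else:
            fids = sorted({h.feature_id for h in best})
            share = n / len(fids)
            for fid in fids:
                result.other_counts[fid] = result.other_counts.get(fid, 0.0) + share
                result.feature_classes[fid] = cls
    return result


def complete_report(report: QCReport, result: AnnotationResult) -> QCReport:
    """Fill the mapping/class half of a QCReport from an AnnotationResult."""
    report.n_unmapped = result.n_unmapped
    report.n_unique = result.n_unique
    report.n_multi = result.n_multi
    report.class_read_counts = dict(result.class_read_counts)
    report.mirna_count_ge1 = result.mirna_detected(1)
    report.mirna_count_ge10 = result.mirna_detected(10)
    report.mirna_count_ge20 = result.mirna_detected(20)
    report.annotated = True
    return report
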