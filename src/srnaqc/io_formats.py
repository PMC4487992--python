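"""Readers and writers for every on-disk format the pipeline touches.

Formats: 4-line FASTQ (Phred+33, optionally gzipped), reference FASTA with a
tab-separated sidecar class map, tab-separated count matrices, and QC reports
as JSON plus a fixed-row TSV table.

The class map is a sidecar file rather than something parsed out of FASTA
headers: miRBase, Rfam and repeat-database header dialects all differ, and a
two/three-column TSV (``feature_id  class  [mature_name]``) is unambiguous.
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: The closed set of annotation classes a reference feature may carry.
RNA_CLASSES = ("miRNA", "other_ncRNA", "repeat", "coding", "unannotated")

#: How each class is labelled in report tables ("unannotated" reads are
#: reported as "Unknown", matching standard small RNA pipeline summaries).
CLASS_REPORT_LABELS = {
    "miRNA": "miRNA",
    "other_ncRNA": "Other ncRNAs",
    "repeat": "Repeat",
    "coding": "Coding Gene",
    "unannotated": "Unknown",
}

MAX_PHRED = 60
_VALID_BASES = frozenset("ACGTN")


class FastqParseError(ValueError):
    """Raised for malformed FASTQ input (truncated record, bad qualities)."""


class ReferenceError(ValueError):
    """Raised for an inconsistent reference set or class map."""


# ---------------------------------------------------------------------------
# Reads


@dataclass
class Read:
    """One single-end sequencing read.

    Attributes
    ----------
    id : str
        Read identifier (text up to the first whitespace of the FASTQ title).
    seq : str
        Base string over ``{A, C, G, T, N}``.
    quals : numpy.ndarray
        Integer Phred scores, one per base, in ``[0, 60]``.
    """

    id: str
    seq: str
    quals: np.ndarray

    def __len__(self) -> int:
        return len(self.seq)


def quals_from_string(qual: str) -> np.ndarray:
    """Decode a Phred+33 quality string into integer scores."""
    return (
        np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    )


def quals_to_string(quals: np.ndarray) -> str:
    """Encode integer Phred scores as a Phred+33 string."""
    arr = np.asarray(quals, dtype=np.int16) + 33
    return arr.astype(np.uint8).tobytes().decode("ascii")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a 4-line Phred+33 FASTQ file (plain or gzipped).

    Yields reads in file order; ``N`` bases are preserved. A truncated record
    or a sequence/quality length mismatch raises :class:`FastqParseError`
    naming the record index. Quality characters implying Phred > 60 raise an
    error as well — such files are almost certainly Phred+64, which this
    pipeline (built for Phred+33 instruments) deliberately rejects.
    """
    with _open_text(path) as handle:
        index = 0
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"record {index}: {exc}") from exc
            quals = quals_from_string(qual)
            if quals.size and int(quals.max()) > MAX_PHRED:
                raise FastqParseError(
                    f"record {index}: Phred score {int(quals.max())} > {MAX_PHRED}; "
                    "input looks Phred+64-encoded, only Phred+33 is supported"
                )
            if quals.size and int(quals.min()) < 0:
                raise FastqParseError(f"record {index}: negative Phred score")
            yield Read(id=title.split()[0], seq=seq.upper(), quals=quals)
            index += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as 4-line Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            handle.write(
                f"@{read.id}\n{read.seq}\n+\n{quals_to_string(read.quals)}\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# Reference sets


@dataclass(frozen=True)
class RefRecord:
    """One classed reference sequence.

    ``mature_name`` collapses multi-locus miRNAs: identical mature sequences
    encoded at several genomic loci share one mature name and are counted as
    one miRNA. For non-miRNA classes it defaults to the feature id.
    """

    feature_id: str
    seq: str
    rna_class: str
    mature_name: str


@dataclass
class ReferenceDB:
    """A validated collection of classed small RNA reference sequences."""

    records: list[RefRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.feature_id in seen:
                raise ReferenceError(f"duplicate feature_id {rec.feature_id!r}")
            seen.add(rec.feature_id)
            if rec.rna_class not in RNA_CLASSES:
                raise ReferenceError(
                    f"unknown class {rec.rna_class!r} for {rec.feature_id!r}; "
                    f"expected one of {RNA_CLASSES}"
                )
            bad = set(rec.seq) - _VALID_BASES
            if bad:
                raise ReferenceError(
                    f"{rec.feature_id!r}: invalid bases {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RefRecord]:
        return iter(self.records)

    @property
    def by_id(self) -> dict[str, RefRecord]:
        return {rec.feature_id: rec for rec in self.records}

    def mature_groups(self) -> dict[str, list[str]]:
        """Map each miRNA mature name to the feature ids that carry it."""
        groups: dict[str, list[str]] = {}
        for rec in self.records:
            if rec.rna_class == "miRNA":
                groups.setdefault(rec.mature_name, []).append(rec.feature_id)
        return groups


def read_reference(
    fasta_path: str | Path,
    classmap_path: str | Path,
    case_fold_classes: bool = False,
) -> ReferenceDB:
    """Load a FASTA reference plus its sidecar class map into a ReferenceDB.

    Every FASTA id must appear in the class map. ``U`` residues (RNA
    alphabets, as in miRBase) are converted to ``T``. Class labels must match
    :data:`RNA_CLASSES` exactly unless ``case_fold_classes`` is set.
    """
    classes: dict[str, str] = {}
    matures: dict[str, str] = {}
    canonical = {c.lower(): c for c in RNA_CLASSES}
    with _open_text(classmap_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "feature_id":  # header row
                continue
            if len(fields) < 2:
                raise ReferenceError(
                    f"{classmap_path}: line {lineno}: expected "
                    "feature_id<TAB>class[<TAB>mature_name]"
                )
            fid, label = fields[0], fields[1]
            if case_fold_classes and label.lower() in canonical:
                label = canonical[label.lower()]
            if label not in RNA_CLASSES:
                raise ReferenceError(
                    f"{classmap_path}: line {lineno}: unknown class {label!r}"
                )
            classes[fid] = label
            if len(fields) >= 3 and fields[2]:
                matures[fid] = fields[2]

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id not in classes:
            raise ReferenceError(
                f"feature {rec.id!r} present in FASTA but missing from class map"
            )
        records.append(
            RefRecord(
                feature_id=rec.id,
                seq=seq,
                rna_class=classes[rec.id],
                mature_name=matures.get(rec.id, rec.id),
            )
        )
    return ReferenceDB(records)


def write_reference(
    db: ReferenceDB, fasta_path: str | Path, classmap_path: str | Path
) -> None:
    """Write a ReferenceDB as FASTA plus sidecar class map."""
    with _open_text(fasta_path, "wt") as fa:
        for rec in db:
            fa.write(f">{rec.feature_id}\n{rec.seq}\n")
    with _open_text(classmap_path, "wt") as cm:
        cm.write("feature_id\tclass\tmature_name\n")
        for rec in db:
            cm.write(f"{rec.feature_id}\t{rec.rna_class}\t{rec.mature_name}\n")


# ---------------------------------------------------------------------------
# QC report


#: Row labels of the per-library QC summary table, in output order.
QC_TABLE_ROWS = (
    "Raw Reads",
    "Size (<15 nt)",
    "Low Quality (Q <30)",
    "Adapter-Adapter",
    "RNAs >40 nt",
    "Surviving Reads",
    "Unmapped",
    "Unique-Mapped",
    "Multi-Mapped",
    "miRNA",
    "Other ncRNAs",
    "Repeat",
    "Coding Gene",
    "Unknown",
    "miRNA Count",
)


@dataclass
class QCReport:
    """Per-library accounting: read filtering, mapping and class breakdown.

    Counts are stored exactly; percentages are derived properties and rounded
    only at serialization (2 decimal places). Filter-category percentages are
    taken over raw reads; mapping-status and class percentages over surviving
    reads, so that ``unmapped% + Σ class% = 100`` and
    ``unique% + multi% + unmapped% = 100`` up to rounding.
    """

    library_id: str = ""
    raw_reads: int = 0
    n_too_short: int = 0
    n_low_quality: int = 0
    n_dimer: int = 0
    n_long_rna: int = 0
    n_surviving: int = 0
    mean_quality: float = float("nan")
    # mapping stage (filled by annotate)
    n_unmapped: int = 0
    n_unique: int = 0
    n_multi: int = 0
    class_read_counts: dict[str, int] = field(default_factory=dict)
    mirna_count_ge1: int = 0
    mirna_count_ge10: int = 0
    mirna_count_ge20: int = 0
    annotated: bool = False

    # -- derived percentages -------------------------------------------------

    def _pct_raw(self, n: int) -> float:
        return 100.0 * n / self.raw_reads if self.raw_reads else 0.0

    def _pct_surv(self, n: float) -> float:
        return 100.0 * n / self.n_surviving if self.n_surviving else 0.0

    @property
    def pct_too_short(self) -> float:
        return self._pct_raw(self.n_too_short)

    @property
    def pct_low_quality(self) -> float:
        return self._pct_raw(self.n_low_quality)

    @property
    def pct_dimer(self) -> float:
        return self._pct_raw(self.n_dimer)

    @property
    def pct_long_rna(self) -> float:
        return self._pct_raw(self.n_long_rna)

    @property
    def pct_surviving(self) -> float:
        return self._pct_raw(self.n_surviving)

    @property
    def pct_unmapped(self) -> float:
        return self._pct_surv(self.n_unmapped)

    @property
    def pct_unique(self) -> float:
        return self._pct_surv(self.n_unique)

    @property
    def pct_multi(self) -> float:
        return self._pct_surv(self.n_multi)

    def pct_class(self, rna_class: str) -> float:
        return self._pct_surv(self.class_read_counts.get(rna_class, 0))

    def category_counts(self) -> dict[str, int]:
        return {
            "dimer": self.n_dimer,
            "too_short": self.n_too_short,
            "low_quality": self.n_low_quality,
            "long_rna": self.n_long_rna,
            "surviving": self.n_surviving,
        }

    def to_dict(self) -> dict:
        """Full JSON-serializable view (counts and derived percentages)."""
        d = {
            "library_id": self.library_id,
            "raw_reads": self.raw_reads,
            "mean_quality": None
            if math.isnan(self.mean_quality)
            else round(self.mean_quality, 2),
            "counts": {
                **self.category_counts(),
                "unmapped": self.n_unmapped,
                "unique_mapped": self.n_unique,
                "multi_mapped": self.n_multi,
                "classes": dict(sorted(self.class_read_counts.items())),
            },
            "percent": {
                "size_lt_min": round(self.pct_too_short, 2),
                "low_quality": round(self.pct_low_quality, 2),
                "adapter_adapter": round(self.pct_dimer, 2),
                "rnas_gt_max": round(self.pct_long_rna, 2),
                "surviving": round(self.pct_surviving, 2),
                "unmapped": round(self.pct_unmapped, 2),
                "unique_mapped": round(self.pct_unique, 2),
                "multi_mapped": round(self.pct_multi, 2),
                "classes": {
                    c: round(self.pct_class(c), 2) for c in RNA_CLASSES
                },
            },
            "mirna_count_ge1": self.mirna_count_ge1,
            "mirna_count_ge10": self.mirna_count_ge10,
            "mirna_count_ge20": self.mirna_count_ge20,
            "annotated": self.annotated,
        }
        if self.raw_reads == 0:
            d["empty"] = True
        return d

    def table_column(self) -> dict[str, str]:
        """The report as a Table-style column keyed by :data:`QC_TABLE_ROWS`."""

        def pct(x: float) -> str:
            return f"{x:.2f} %"

        return {
            "Raw Reads": str(self.raw_reads),
            "Size (<15 nt)": pct(self.pct_too_short),
            "Low Quality (Q <30)": pct(self.pct_low_quality),
            "Adapter-Adapter": pct(self.pct_dimer),
            "RNAs >40 nt": pct(self.pct_long_rna),
            "Surviving Reads": pct(self.pct_surviving),
            "Unmapped": pct(self.pct_unmapped),
            "Unique-Mapped": pct(self.pct_unique),
            "Multi-Mapped": pct(self.pct_multi),
            "miRNA": pct(self.pct_class("miRNA")),
            "Other ncRNAs": pct(self.pct_class("other_ncRNA")),
            "Repeat": pct(self.pct_class("repeat")),
            "Coding Gene": pct(self.pct_class("coding")),
            "Unknown": pct(self.pct_class("unannotated")),
            "miRNA Count": str(self.mirna_count_ge1),
        }


def write_qc_report(report: QCReport, prefix: str | Path) -> None:
    """Write a QCReport as ``<prefix>.json`` and ``<prefix>.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.parent / (prefix.name + ".json"), "w") as jf:
        json.dump(report.to_dict(), jf, indent=2, sort_keys=True)
        jf.write("\n")
    column = report.table_column()
    with open(prefix.parent / (prefix.name + ".tsv"), "w") as tf:
        tf.write(f"Metric\t{report.library_id or 'value'}\n")
        for row in QC_TABLE_ROWS:
            tf.write(f"{row}\t{column[row]}\n")


def write_qc_table(reports: Iterable[QCReport], path: str | Path) -> None:
    """Write several libraries side by side as one QC summary table."""
    reports = list(reports)
    columns = [r.table_column() for r in reports]
    with open(path, "w") as tf:
        tf.write("Metric\t" + "\t".join(r.library_id for r in reports) + "\n")
        for row in QC_TABLE_ROWS:
            tf.write(row + "\t" + "\t".join(c[row] for c in columns) + "\n")


# ---------------------------------------------------------------------------
# Count matrices


@dataclass
class CountMatrix:
    """Features × libraries counts with per-feature class labels.

    Counts are floats because multi-mapped reads may contribute fractional
    counts; they are rounded only when serialized with ``decimals`` set.
    ``metadata`` optionally carries per-library annotations (tissue, RIN).
    """

    counts: pd.DataFrame
    classes: pd.Series
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()]
            raise ValueError(f"duplicate library ids: {sorted(set(dupes))}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        self.classes = self.classes.reindex(self.counts.index)
        if self.classes.isna().any():
            missing = self.classes[self.classes.isna()].index.tolist()
            raise ValueError(f"features missing a class label: {missing[:5]}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def subset_class(self, rna_class: str) -> "CountMatrix":
        mask = self.classes == rna_class
        return CountMatrix(
            self.counts.loc[mask], self.classes.loc[mask], self.metadata
        )


def write_counts(
    matrix: CountMatrix, path: str | Path, decimals: int | None = None
) -> None:
    """Write a count matrix as TSV: feature_id, class, one column per library."""
    df = matrix.counts.copy()
    if decimals is not None:
        df = df.round(decimals)
    out = pd.concat([matrix.classes.rename("class"), df], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing 'class' column")
    classes = df["class"].astype(str)
    counts = df.drop(columns=["class"]).astype(float)
    counts.index.name = None
    classes.index.name = None
    return CountMatrix(counts=counts, classes=classes)
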