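"""Synthetic classed references and FASTQ libraries with ground-truth manifests.

The generator emulates the structure of TruSeq small RNA libraries sequenced
as 50 nt single-end reads: each read is an insert, followed by the 3' adapter,
followed by read-through content (the remaining adapter bases, then an ``A``
fill). Five mutually exclusive per-read artifact classes are drawn from a
categorical distribution:

``dimer``
    Adapter-adapter ligation product: the read starts with the adapter.
``short``
    Degraded fragment: 1–14 nt random insert.
``lowq``
    A normal molecule sequenced with low quality (per-read mean Phred drawn
    around ``q_low_mean`` < 30).
``long_rna``
    An insert long enough that no complete 10-mer of adapter remains in the
    read — emulating mid-size/large ncRNA carried through size selection.
``clean``
    A feature-derived insert with good qualities; these are the reads the
    QC stage should emit and the annotation stage should count.

Feature abundance is heavily skewed, as in whole blood where a single miRNA
family dominates: the top miRNA receives ``abundance_skew`` of the clean-read
mass, the remainder is split across annotation classes (``class_mixture``)
and, within a class, across features by a Zipf-like 1/rank law. A small
``unmapped`` pseudo-class emits random inserts matching no reference, so the
annotation stage has true negatives.

Per-read qualities are constant across the read, with the per-read mean drawn
from a normal (sd 1.5) around ``q_good_mean`` or ``q_low_mean`` and clipped to
[2, 40] — the QC filters act on mean quality only, so per-cycle decay is
deliberately not modelled.

Everything is driven by one ``numpy`` Generator per call: the same seed gives
byte-identical FASTA/FASTQ/manifest output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .io_formats import (
    Read,
    RefRecord,
    ReferenceDB,
    write_fastq,
    write_reference,
)
from .qc_filter import TRUSEQ_SMALL_RNA_ADAPTER

_BASES = np.array(list("ACGT"))

#: Manifest artifact label -> QC category it should land in.
QC_CATEGORY_FOR_ARTIFACT = {
    "dimer": "dimer",
    "short": "too_short",
    "lowq": "low_quality",
    "long_rna": "long_rna",
    "clean": "surviving",
}

#: Default clean-read class composition, including an "unmapped" pseudo-class
#: of random inserts. Chosen to resemble a typical good-quality whole-blood
#: library (miRNA-dominated, ~1–2 % unmapped, traces of other classes).
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "miRNA": 0.956,
    "other_ncRNA": 0.004,
    "repeat": 0.008,
    "coding": 0.0005,
    "unannotated": 0.005,
    "unmapped": 0.013,
}


class ConfigurationError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class RefConfig:
    """Configuration of a synthetic classed reference set.

    Lengths: miRNAs are drawn uniformly from ``mirna_len_range`` (default
    19–25 nt, the mature-miRNA peak); all other classes from
    ``other_len_range`` (default 24–40 nt, covering piRNA-sized and longer
    small RNAs while staying inside the 15–40 nt surviving window).
    ``n_multilocus_mirna`` adds duplicate-sequence miRNA records sharing one
    mature name, emulating mature sequences encoded at several loci.
    """

    n_mirna: int = 300
    n_other_ncrna: int = 100
    n_repeat: int = 50
    n_coding: int = 30
    n_unannotated: int = 50
    mirna_len_range: tuple[int, int] = (19, 25)
    other_len_range: tuple[int, int] = (24, 40)
    n_multilocus_mirna: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_mirna,
            self.n_other_ncrna,
            self.n_repeat,
            self.n_coding,
            self.n_unannotated,
            self.n_multilocus_mirna,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("feature counts must be >= 0")
        for lo, hi in (self.mirna_len_range, self.other_len_range):
            if lo > hi:
                raise ConfigurationError(f"invalid length range {lo}–{hi}")
        if self.n_multilocus_mirna > self.n_mirna:
            raise ConfigurationError("n_multilocus_mirna > n_mirna")


@dataclass(frozen=True)
class LibraryConfig:
    """Configuration of one synthetic FASTQ library.

    Artifact probabilities default to rates typical of a bead-purified
    whole-blood library: a trace of adapter dimers, a few percent of degraded
    and low-quality reads, and a substantial long-RNA fraction.
    """

    n_reads: int = 100_000
    read_len: int = 50
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    abundance_skew: float = 0.9
    p_dimer: float = 0.005
    p_short: float = 0.02
    p_lowq: float = 0.015
    p_long: float = 0.20
    q_good_mean: float = 37.0
    q_low_mean: float = 25.0
    seq_error_rate: float = 0.0
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    #: feature id of the dominant miRNA (different tissues have different
    #: dominant families); default: the first eligible miRNA in the reference
    top_feature: str | None = None
    #: within-class abundance decay 1/rank**rank_exponent; 1.5 yields the
    #: long tail of lowly-expressed features that makes detection depth- and
    #: threshold-dependent, as in real small RNA libraries
    rank_exponent: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ConfigurationError("n_reads must be >= 0")
        probs = (self.p_dimer, self.p_short, self.p_lowq, self.p_long)
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigurationError("artifact probabilities must be in [0, 1]")
        if sum(probs) > 1 + 1e-12:
            raise ConfigurationError(
                "p_dimer + p_short + p_lowq + p_long must be <= 1"
            )
        if not 0 <= self.abundance_skew < 1:
            raise ConfigurationError("abundance_skew must be in [0, 1)")
        if self.read_len < 10 + 15:
            raise ConfigurationError("read_len must be >= adapter seed + 15")
        if not 0 <= self.seq_error_rate < 1:
            raise ConfigurationError("seq_error_rate must be in [0, 1)")
        if any(w < 0 for w in self.class_mixture.values()):
            raise ConfigurationError("class_mixture weights must be >= 0")

    @property
    def p_clean(self) -> float:
        return 1.0 - (self.p_dimer + self.p_short + self.p_lowq + self.p_long)


@dataclass
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    artifact: str  # dimer | short | lowq | long_rna | clean
    feature_id: str  # "" for feature-less reads
    source_class: str  # RNA class, "unmapped", or ""
    insert_len: int


@dataclass
class TruthManifest:
    """Per-read ground truth plus the aggregate expectations of a library."""

    records: list[TruthRecord]
    expected_fractions: dict[str, float]
    true_feature_counts: dict[str, int]
    true_mature_counts: dict[str, int]

    def category_counts(self) -> dict[str, int]:
        counts = {a: 0 for a in QC_CATEGORY_FOR_ARTIFACT}
        for rec in self.records:
            counts[rec.artifact] += 1
        return counts

    def category_fractions(self) -> dict[str, float]:
        n = len(self.records)
        return {
            a: (c / n if n else 0.0) for a, c in self.category_counts().items()
        }

    def clean_class_counts(self) -> dict[str, int]:
        """Clean-read counts per source class (including "unmapped")."""
        counts: dict[str, int] = {}
        for rec in self.records:
            if rec.artifact == "clean":
                counts[rec.source_class] = counts.get(rec.source_class, 0) + 1
        return counts

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write("read_id\tartifact\tfeature_id\tsource_class\tinsert_len\n")
            for r in self.records:
                handle.write(
                    f"{r.read_id}\t{r.artifact}\t{r.feature_id}\t"
                    f"{r.source_class}\t{r.insert_len}\n"
                )

    def write_json_summary(self, path: str | Path) -> None:
        summary = {
            "n_reads": len(self.records),
            "expected_fractions": self.expected_fractions,
            "category_counts": self.category_counts(),
            "clean_class_counts": dict(sorted(self.clean_class_counts().items())),
            "true_feature_counts": dict(sorted(self.true_feature_counts.items())),
            "true_mature_counts": dict(sorted(self.true_mature_counts.items())),
        }
        with open(path, "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
            handle.write("\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _draw_unique_seq(
    rng: np.random.Generator,
    length: int,
    used: set[str],
    forbidden_motif: str,
) -> str:
    while True:
        seq = _random_seq(rng, length)
        if seq not in used and forbidden_motif not in seq:
            used.add(seq)
            return seq


def generate_reference(config: RefConfig) -> ReferenceDB:
    """Generate a classed reference set; deterministic given ``config.seed``.

    Sequences are unique per feature (the optional multi-locus miRNA records
    deliberately duplicate an existing mature sequence under a new feature id
    with the same mature name). Generated sequences never contain the default
    TruSeq adapter's 10 nt seed, so adapter detection in downstream synthetic
    reads is unambiguous.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    used: set[str] = set()
    motif = TRUSEQ_SMALL_RNA_ADAPTER[:10]
    records: list[RefRecord] = []

    lo, hi = config.mirna_len_range
    for i in range(config.n_mirna):
        seq = _draw_unique_seq(rng, int(rng.integers(lo, hi + 1)), used, motif)
        name = f"miR-{i + 1}"
        records.append(RefRecord(f"mir-{i + 1:04d}", seq, "miRNA", name))

    lo, hi = config.other_len_range
    for prefix, n, rna_class in (
        ("ncrna", config.n_other_ncrna, "other_ncRNA"),
        ("rep", config.n_repeat, "repeat"),
        ("cds", config.n_coding, "coding"),
        ("unk", config.n_unannotated, "unannotated"),
    ):
        for i in range(n):
            seq = _draw_unique_seq(rng, int(rng.integers(lo, hi + 1)), used, motif)
            fid = f"{prefix}-{i + 1:04d}"
            records.append(RefRecord(fid, seq, rna_class, fid))

    # Multi-locus miRNAs: duplicate the sequence of an existing miRNA under a
    # second feature id sharing the mature name.
    mirnas = [r for r in records if r.rna_class == "miRNA"]
    for i in range(config.n_multilocus_mirna):
        src = mirnas[i % len(mirnas)]
        records.append(
            RefRecord(f"{src.feature_id}-loc2", src.seq, "miRNA", src.mature_name)
        )
    return ReferenceDB(records)


def _abundance_vector(
    ref: ReferenceDB, cfg: LibraryConfig
) -> tuple[list[RefRecord | None], np.ndarray]:
    """Clean-read sampling distribution over eligible features.

    Returns parallel lists of feature records (``None`` denotes the random
    "unmapped" pseudo-feature) and their probabilities. The first eligible
    miRNA is the top feature and receives ``abundance_skew`` of the mass;
    the rest is split by ``class_mixture`` and a 1/rank law within class.
    """
    max_insert = min(40, cfg.read_len - 10)
    eligible: dict[str, list[RefRecord]] = {}
    for rec in ref:
        if 15 <= len(rec.seq) <= max_insert:
            eligible.setdefault(rec.rna_class, []).append(rec)

    mixture = {k: float(v) for k, v in cfg.class_mixture.items()}
    present = {
        c: w
        for c, w in mixture.items()
        if (c == "unmapped" and w > 0) or (eligible.get(c) and w > 0)
    }
    total = sum(present.values())
    if total <= 0:
        raise ConfigurationError("class_mixture has no usable mass")
    present = {c: w / total for c, w in present.items()}

    skew = cfg.abundance_skew
    top: RefRecord | None = None
    if skew > 0:
        if not eligible.get("miRNA"):
            raise ConfigurationError(
                "abundance_skew > 0 requires at least one eligible miRNA"
            )
        if cfg.top_feature is None:
            top = eligible["miRNA"][0]
        else:
            matches = [
                r for r in eligible["miRNA"] if r.feature_id == cfg.top_feature
            ]
            if not matches:
                raise ConfigurationError(
                    f"top_feature {cfg.top_feature!r} is not an eligible miRNA"
                )
            top = matches[0]

    residual = dict(present)
    if top is not None:
        residual["miRNA"] = max(residual.get("miRNA", 0.0) - skew, 0.0)
    res_total = sum(residual.values())

    features: list[RefRecord | None] = []
    probs: list[float] = []
    if top is not None:
        features.append(top)
        probs.append(skew)
    rest_mass = 1.0 - (skew if top is not None else 0.0)
    for rna_class in sorted(residual):
        mass = (
            residual[rna_class] / res_total * rest_mass if res_total > 0 else 0.0
        )
        if mass <= 0:
            continue
        if rna_class == "unmapped":
            features.append(None)
            probs.append(mass)
            continue
        members = [r for r in eligible[rna_class] if r is not top]
        if not members:
            continue
        weights = 1.0 / np.arange(1, len(members) + 1) ** cfg.rank_exponent
        weights /= weights.sum()
        for rec, w in zip(members, weights):
            features.append(rec)
            probs.append(mass * w)
    probs_arr = np.asarray(probs, dtype=float)
    probs_arr /= probs_arr.sum()
    return features, probs_arr


def generate_library(
    ref: ReferenceDB, cfg: LibraryConfig, library_id: str = "lib"
) -> tuple[list[Read], TruthManifest]:
    """Simulate one FASTQ library and its per-read ground-truth manifest."""
    cfg.validate()
    if cfg.n_reads > 0 and len(ref) == 0 and cfg.p_clean > 0:
        raise ConfigurationError("cannot generate clean reads from an empty reference")
    rng = np.random.default_rng(cfg.seed)

    p_clean = cfg.p_clean
    cat_probs = np.array(
        [cfg.p_dimer, cfg.p_short, cfg.p_lowq, cfg.p_long, max(p_clean, 0.0)]
    )
    cat_probs /= cat_probs.sum()
    cat_names = ("dimer", "short", "lowq", "long_rna", "clean")
    categories = rng.choice(5, size=cfg.n_reads, p=cat_probs)

    need_features = (categories == 2) | (categories == 4)  # lowq or clean
    features: list[RefRecord | None] = []
    probs = np.empty(0)
    if need_features.any():
        features, probs = _abundance_vector(ref, cfg)
    feature_draws = (
        rng.choice(len(features), size=cfg.n_reads, p=probs)
        if len(features)
        else np.zeros(cfg.n_reads, dtype=int)
    )

    mean_quals = np.clip(
        np.where(
            categories == 2,
            rng.normal(cfg.q_low_mean, 1.5, size=cfg.n_reads),
            rng.normal(cfg.q_good_mean, 1.5, size=cfg.n_reads),
        ),
        2,
        40,
    ).round().astype(int)

    max_insert = min(40, cfg.read_len - 10)
    long_lo = cfg.read_len - 9  # leaves < 10 adapter bases in the read
    adapter = cfg.adapter

    def assemble(insert: str) -> str:
        return (insert + adapter + "A" * cfg.read_len)[: cfg.read_len]

    def mutate(seq: str) -> str:
        if cfg.seq_error_rate <= 0:
            return seq
        out = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < cfg.seq_error_rate)[0]
        for pos in hits:
            out[pos] = _BASES[
                (np.flatnonzero(_BASES == seq[pos])[0] + rng.integers(1, 4)) % 4
            ]
        return "".join(out)

    reads: list[Read] = []
    records: list[TruthRecord] = []
    feature_counts: dict[str, int] = {}
    mature_counts: dict[str, int] = {}
    for i in range(cfg.n_reads):
        cat = cat_names[categories[i]]
        read_id = f"{library_id}:{i:07d}"
        feature_id, source_class = "", ""
        if cat == "dimer":
            insert = ""
        elif cat == "short":
            insert = _random_seq(rng, int(rng.integers(1, 15)))
        elif cat == "long_rna":
            insert = _random_seq(rng, int(rng.integers(long_lo, cfg.read_len + 1)))
        else:  # lowq or clean: a feature-derived (or unmapped) molecule
            rec = features[feature_draws[i]]
            if rec is None:
                insert = _random_seq(rng, int(rng.integers(15, max_insert + 1)))
                source_class = "unmapped"
            else:
                insert = mutate(rec.seq)
                feature_id, source_class = rec.feature_id, rec.rna_class
            if cat == "clean":
                if rec is not None:
                    feature_counts[feature_id] = feature_counts.get(feature_id, 0) + 1
                    if rec.rna_class == "miRNA":
                        mature_counts[rec.mature_name] = (
                            mature_counts.get(rec.mature_name, 0) + 1
                        )
        seq = assemble(insert)
        quals = np.full(cfg.read_len, mean_quals[i], dtype=np.int16)
        reads.append(Read(id=read_id, seq=seq, quals=quals))
        records.append(TruthRecord(read_id, cat, feature_id, source_class, len(insert)))

    expected = {
        "dimer": cfg.p_dimer,
        "short": cfg.p_short,
        "lowq": cfg.p_lowq,
        "long_rna": cfg.p_long,
        "clean": p_clean,
    }
    manifest = TruthManifest(
        records=records,
        expected_fractions=expected,
        true_feature_counts=feature_counts,
        true_mature_counts=mature_counts,
    )
    return reads, manifest


def simulate_to_dir(
    ref_config: RefConfig,
    library_configs: Mapping[str, LibraryConfig],
    outdir: str | Path,
) -> ReferenceDB:
    """Generate a reference plus named libraries and write everything under
    ``outdir`` (FASTA + class map, per-library FASTQ and manifests)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = generate_reference(ref_config)
    write_reference(ref, outdir / "reference.fasta", outdir / "reference.classes.tsv")
    for lib_id, cfg in library_configs.items():
        reads, manifest = generate_library(ref, cfg, library_id=lib_id)
        write_fastq(reads, outdir / f"{lib_id}.fastq")
        manifest.write_tsv(outdir / f"{lib_id}.manifest.tsv")
        manifest.write_json_summary(outdir / f"{lib_id}.manifest.json")
    return ref
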