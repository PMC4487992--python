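# Methods

This note documents the models and procedures `srnaqc` implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Read model and QC filters

A library is modelled as 50 nt single-end Phred+33 reads with TruSeq small
RNA structure: biological insert, then the 3′ adapter
`TGGAATTCTCGGGTGCCAAGG`, then read-through content. Adapter detection is a
perfect match of the adapter's first `adapter_seed_len = 10` bases, leftmost
occurrence. Four filters partition every read into exactly one category:

| filter | rule | default |
|---|---|---|
| adapter-adapter | adapter seed at position 0 | — |
| size | insert length < `min_len` | 15 nt |
| long RNA | no adapter seed found, or insert > `max_len` | 40 nt |
| quality | mean insert Phred < `min_mean_q` | Q30 |

Decisions taken where conventions differ between tools:

* **Precedence** is adapter-detection → dimer → size → quality, so the
  categories are mutually exclusive and sum exactly to the raw read count.
* **Boundaries**: reads *below* the cutoffs are removed — inserts of exactly
  15 and exactly 40 nt survive, as does mean quality exactly 30.0.
* **"No adapter" ≡ "RNA >40 nt"**: with 50 nt reads and a 10 nt seed, any
  insert longer than 40 nt leaves fewer than 10 adapter bases, so the two
  descriptions coincide; both are reported under one category. For longer
  reads the two rules can diverge; `max_len` and the seed length are both
  configurable.
* **Quality scope**: the filter evaluates the mean over the trimmed insert
  (the biologically relevant bases); the per-library "average quality" in
  reports is the mean of per-read means over raw reads.

Percentages in the QC report are exact internally and rounded to two
decimals only at serialization. Category percentages are taken over raw
reads; mapping-status and class percentages over surviving reads, giving the
identities `Σ category % = 100`, `unmapped + unique + multi = 100` and
`unmapped + Σ class % = 100`.

## Annotation

The pipeline matches inserts directly against a classed reference set
rather than a genome: each reference sequence carries one of five classes
(miRNA, other ncRNA, repeat, coding, unannotated — the last reported as
"Unknown"), and "unannotated" decoy references play the role of
genome-mapped-but-unclassified sequence. This keeps the accounting semantics
of a genome pipeline at desk scale.

Matching is Hamming distance within `max_mismatches` (default 1; 0 for
exactness tests), in **containment mode** by default — the insert may occur
at any offset inside a longer reference, since mature miRNAs are substrings
of their hairpin precursors; an equal-length mode is available. A k-mer
index (k = 10) proposes candidates; each candidate is verified by early-abort
Hamming over admissible offsets. Completeness: with no mismatches any window
of a matching insert is an exact k-mer hit; with `mm` mismatches at most
`k·mm` windows can be destroyed, so window seeding is complete when
`L − k + 1 > k·mm`. Shorter inserts at `mm ≥ 1` fall back to scanning all
references, preserving exact agreement with a brute-force scan (verified
against an independent exhaustive-scan oracle in the tests). Libraries are
deduplicated by insert sequence before alignment, so the per-read cost is
amortized over the (heavily duplicated) read population.

One class per read is assigned among the *minimum-mismatch* hits, by the
priority miRNA > other ncRNA > repeat > coding > unannotated — mirroring
pipelines that consult miRBase before Rfam and repeat annotations. A read is
uniquely mapped when its best hits name one feature or (for miRNAs) one
mature name; identical mature sequences at multiple loci therefore count as
one miRNA regardless of locus multiplicity. When best hits tie across
distinct mature names (or features), the read contributes 1/n to each, so
every read adds exactly one count at each accounting level. The fractional
split is a documented choice: no standard assignment rule exists for this
situation, and splitting avoids double counting.

## Quantification and normalization

Counts are assembled feature × library (mature-name level for miRNAs,
feature level otherwise; fractional values from tied multi-mappers are kept
as-is). Detection at threshold t requires count ≥ t in **every** library
(`all_libraries`), the strict rule appropriate for cross-library panels; an
`any_library` scope supports per-tissue detection. Detected sets are nested
across thresholds by construction.

Size factors are the median-of-ratios estimator: per library, the median
over features positive in all libraries of the ratio between the library's
count and the feature's across-library geometric mean, computed in log
space. The returned factors are rescaled to geometric mean 1: the overall
scale of size factors is an arbitrary gauge (only between-library ratios
matter), and pinning it makes normalization exactly idempotent —
re-estimating factors on a normalized matrix returns 1 for every library.
One consequence worth knowing: artificially scaling one of m libraries by c
is undone only up to a global `c^(1/m)` on the normalized matrix, because
the geometric-mean reference itself shifts; the between-library structure is
recovered exactly. If no feature is positive in all libraries the estimator
has no support and raises; a pseudocount option exists for sparse matrices.
No dispersion estimation or differential testing is performed.

## Depth saturation

Reducing a library of N mapped reads to m reads is sampling without
replacement, so the subsampled count of a feature with n_i reads is
`Hypergeom(N, n_i, m)` and the expected number of features detected at
threshold t is `Σ_i P(X_i ≥ t)`. For t = 1 this reduces to the classic
rarefaction formula `Σ_i 1 − C(N−n_i, m)/C(N, m)`; all tail probabilities
are evaluated in log space (scipy), stable at N ~ 1e7. Monte-Carlo mode
draws multivariate hypergeometric replicates and reports their mean and
spread next to the analytic expectation. The default depth grid is the
available total scaled by (1, 1/2, 1/4, 1/8, 1/12) — the halving ladder that
corresponds to doubling the number of samples pooled per sequencing lane.
Pooled-across-libraries curves are the default; fractional counts are
rounded to integers for subsampling. Extrapolation beyond the observed depth
(richness estimators) is out of scope.

## Tissue profiling

A feature is "detected in tissue T" when it reaches the threshold in every
replicate library of T (default), or in any replicate (`any_replicate`) —
the strict rule is consistent with the all-libraries detection convention,
but the choice is genuinely open for replicate panels, so both ship and the
rule in force is recorded in every output header. Expression fractions are
computed on replicate-summed counts within one class. Venn partitions
support 2–4 named sets (the four-tissue design); regions are exact
memberships and partition the union. Co-expression of tissues A and B is
reported as `|A∩B|` and `100·|A∩B|/|A|` — the percentage is always relative
to the first (reference) tissue.

## Synthetic data: what it emulates, and what it does not

The generator draws, per read, one of five mutually exclusive artifact
classes (categorical with probabilities `p_dimer`, `p_short`, `p_lowq`,
`p_long`, remainder clean), then assembles insert + adapter + remaining
adapter bases + `A` fill, truncated to `read_len`. Defaults emulate a
bead-purified whole-blood library: `p_dimer = 0.005`, `p_short = 0.02`,
`p_lowq = 0.015`, `p_long = 0.20`, read length 50, quality means 37 (good) /
25 (low). Long-RNA reads carry inserts of ≥ `read_len − 9` nt so that no
complete adapter 10-mer fits. Reference sequences never contain the default
adapter's 10-mer, so adapter detection in synthetic reads is unambiguous.

Clean (and low-quality) reads sample a feature from a skewed abundance
vector: the dominant miRNA (`top_feature`, share `abundance_skew`, default
0.9 — one family can exceed 90 % of miRNA reads in whole blood), with the
remaining mass split across classes by `class_mixture` (defaults put ~96 %
of clean reads on miRNA, traces on the other classes, and 1.3 % on an
"unmapped" pseudo-class of random inserts) and within a class by a
`1/rank^1.5` law. The exponent matters: it produces a long tail of
lowly-expressed features, so detected-miRNA counts depend strongly on depth
and threshold — the regime in which saturation analysis is informative at
all. Qualities are constant within a read, with the per-read mean drawn from
a normal (sd 1.5, clipped to [2, 40]) around the good or low mean: the
filters act on mean quality only, so per-cycle decay would add nothing the
pipeline can see. `seq_error_rate` defaults to 0 so alignment-recovery tests
are exact; a non-zero mode exists for mismatch-tolerance tests.

The truth manifest records, per read, the artifact class, source feature and
insert length, plus the realized clean-read abundance vector. The load-
bearing identity — verified end-to-end in the tests — is that QC on a
generated library reproduces the manifest's category fractions within
binomial sampling error, and annotation reproduces its class mixture and
abundance ranking.

Deliberately **not** emulated: 5′ adapter chemistry, PCR duplication, per-
cycle quality decay, instrument error profiles — and genomic multi-mapping.
The last is the important caveat: in real small RNA-seq more than half of
reads map to multiple genomic loci, but in this genome-free design identical
multi-locus miRNAs collapse to one mature name and count as uniquely
mapped, so the synthetic unique/multi split is nearly all-unique. Passing
tests therefore validate the accounting logic, not the multi-mapping burden
of a real genome aligner. Real-data multi-mapping enters only through
reference sets that genuinely share subsequences.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: references of a few
hundred features, libraries of 2 000–200 000 reads, four-tissue panels of
16 × 30 000 reads — sizes chosen so the full synthetic study executes in
seconds while every statistical check retains power (binomial standard
errors at these n are a fraction of the tested effect sizes). All
randomness flows from numpy Generators seeded from a single top-level seed
via deterministic per-stage child seeds (`SeedSequence` over a stage-label
CRC), so identical configuration and seed reproduce byte-identical FASTQ,
manifests and pipeline outputs.

## Known limitations

* Adapter matching is exact-only by design (a perfect 10 nt seed); there is
  no mismatch-tolerant trimming mode.
* The aligner is built for reference sets of thousands of short sequences,
  not genomes; its fallback path is quadratic in reference count for short
  inserts with mismatches.
* Detection thresholds compare against possibly fractional multi-mapper
  counts; with `max_mismatches = 0` and distinct references this never
  occurs.
* The paper-scale reproduction path (real FASTQ archives plus a miRBase-
  derived classed reference) exercises exactly the same entry point as the
  synthetic runs (`srnaqc run` on on-disk FASTQ), but those inputs must be
  supplied by the user; nothing is downloaded.
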