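# srnaqc

Quality control, annotation, quantification and depth-saturation analysis for
small non-coding RNA sequencing (small RNA-seq), plus a synthetic read
generator with per-read ground truth for validating every stage.

## Who this is for

Small RNA-seq libraries (TruSeq small RNA protocol, 50 nt single-end reads)
are dominated by short inserts — mature miRNAs of 19–25 nt, piRNAs and other
small ncRNAs up to ~40 nt — followed by the 3′ adapter and read-through
content. Before any expression analysis, each read must be adapter-trimmed
and filtered, and the library summarized: how many reads were adapter dimers,
degraded fragments, low quality, or long-RNA carry-over; how many survived;
how they map and to which RNA classes; and how many distinct miRNAs are
detectable at a given threshold and sequencing depth. `srnaqc` implements
that pipeline as a tested Python library and CLI for anyone planning or
evaluating small RNA profiling experiments (e.g. blood-based biomarker
panels).

## What it computes

**Read filters.** Each raw read lands in exactly one category, using a
perfect 10 nt match to the 3′ adapter (`TGGAATTCTCGGGTGCCAAGG`):

* *adapter-adapter* — adapter at position 0 (dimer, no insert);
* *size (<15 nt)* — insert shorter than 15 nt;
* *RNAs >40 nt* — no adapter 10-mer found, or insert longer than 40 nt;
* *low quality* — mean insert Phred score below 30
  (Q relates to the per-base error rate by `p_err = 10^(−Q/10)`);
* *surviving* — the trimmed insert, the input to annotation.

**Annotation.** Surviving inserts are matched against a classed reference
set (miRNA / other ncRNA / repeat / coding / unannotated) by a k-mer-seeded
Hamming matcher that provably agrees with an exhaustive scan; each read is
assigned one class by a miRNA-first priority hierarchy, and unique/multi
mapping status. Multi-locus miRNAs sharing one mature sequence collapse to a
single mature name.

**Quantification.** A features × libraries count matrix; detection at
thresholds ≥1/≥10/≥20 counts in *every* library; median-of-ratios size
factors

```
s_j = median_i ( c_ij / (Π_j c_ij)^(1/m) )
```

(rescaled to geometric mean 1) and the normalized matrix.

**Saturation.** Subsampling m of N reads without replacement makes each
feature's count hypergeometric, so the expected number of detectable
features at depth m and threshold t is `Σ_i P(X_i ≥ t)`, with
`X_i ~ Hypergeom(N, n_i, m)` — the analytic rarefaction curve, with optional
Monte-Carlo replicates.

**Tissue profiling.** Per-tissue detected sets, per-feature expression
fractions, Venn partitions (2–4 tissues), tissue-exclusive counts and
pairwise co-expression `(|A∩B|, 100·|A∩B|/|A|)`.

**Synthetic data.** `srnaqc.synthetic_data` generates classed references and
FASTQ libraries with a per-read truth manifest — adapter dimers, degraded
fragments, low-quality reads, long-RNA carry-over, a heavily skewed
abundance (one miRNA family can hold >90 % of reads, as in whole blood) and
a long tail of lowly-expressed features.

## Worked example

```python
from srnaqc import *

ref = generate_reference(RefConfig(n_mirna=150, n_other_ncrna=50, n_repeat=20,
                                   n_coding=10, n_unannotated=20, seed=7))
reads, truth = generate_library(ref, LibraryConfig(n_reads=50_000, seed=11), "blood_1")
survivors, report = run_qc(reads, QCParams(), library_id="blood_1")
result = annotate_library(survivors, build_index(ref))
complete_report(report, result)
```

prints, via the report fields:

```
raw reads        50000
surviving        75.90 %
adapter-adapter  0.50 %
RNAs >40 nt      20.04 %
unmapped         1.26 %
miRNA            96.95 % of surviving
miRNAs >=1       112
miRNAs >=10      21
top miRNA        miR-1 (93.0 % of miRNA reads)
expected miRNAs >=10 at half depth: 14.9
```

Reading: of 50 000 raw reads, 75.9 % survive the four filters (20 % were
long-RNA carry-over, matching the configured generator rate); 96.95 % of
survivors are miRNA, and one dominant family holds 93 % of miRNA reads —
the whole-blood situation. 112 distinct mature miRNAs appear at ≥1 count
but only 21 reach ≥10, and halving the depth would cut that to ~15: with a
skewed abundance distribution, depth buys detection of the lowly-expressed
tail.

The same flow from the shell:

```bash
srnaqc simulate --config sim.yaml --out data/ --seed 7
srnaqc qc --fastq data/blood_1.fastq --out qc/
srnaqc annotate --inserts qc/blood_1.trimmed.fastq \
    --reference data/reference.fasta --classmap data/reference.classes.tsv \
    --out counts/
srnaqc run --config run.yaml        # full pipeline, one config
```

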