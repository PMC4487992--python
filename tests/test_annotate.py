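"""Reference-set alignment and hierarchical class assignment.

The aligner's contract is exact agreement with an exhaustive Hamming scan;
the scan is implemented independently here as the oracle.
"""

import numpy as np
import pytest
from scipy import stats

from srnaqc import (
    Hit,
    LibraryConfig,
    RefConfig,
    align_insert,
    annotate_library,
    assign_annotation,
    build_index,
    generate_library,
    generate_reference,
    run_qc,
)
from srnaqc.io_formats import RefRecord, ReferenceDB


def brute_force_hits(insert, db, max_mm, containment=True):
    """Exhaustive Hamming scan over every feature and every offset."""
    hits = {}
    for rec in db:
        L, R = len(insert), len(rec.seq)
        offsets = range(R - L + 1) if containment else ([0] if R == L else [])
        best = None
        for off in offsets:
            mm = sum(a != b for a, b in zip(insert, rec.seq[off : off + L]))
            if mm <= max_mm and (best is None or mm < best):
                best = mm
        if best is not None:
            hits[rec.feature_id] = best
    return hits


def mk_mirna(fid, seq, mature=None):
    return RefRecord(fid, seq, "miRNA", mature or fid)


class TestBuildIndex:
    def test_empty_db_gives_empty_index(self):
        idx = build_index(ReferenceDB([]))
        assert len(idx) == 0

    def test_short_reference_listed(self):
        db = ReferenceDB([mk_mirna("tiny", "ACGTACG")])
        with pytest.raises(ValueError, match="tiny"):
            build_index(db, k=10)

    def test_small_k_rejected(self, small_ref):
        with pytest.raises(ValueError):
            build_index(small_ref, k=5)

    def test_every_reference_found_by_self_query(self, small_ref):
        idx = build_index(small_ref, max_mismatches=0)
        for rec in small_ref:
            hits = align_insert(rec.seq, idx)
            assert any(
                h.feature_id == rec.feature_id and h.n_mismatches == 0 for h in hits
            )

    def test_rebuild_is_identical(self, small_ref):
        a = build_index(small_ref)
        b = build_index(small_ref)
        assert a.kmers == b.kmers


class TestAlignInsert:
    def test_unique_exact_hit(self, small_ref):
        idx = build_index(small_ref, max_mismatches=0)
        rec = small_ref.records[0]
        hits = align_insert(rec.seq, idx)
        assert [h.feature_id for h in hits] == [rec.feature_id]
        assert hits[0].n_mismatches == 0

    def test_multilocus_sequence_hits_both_features(self):
        seq = "ACGTACGTACGTACGTACGTA"
        db = ReferenceDB(
            [mk_mirna("loc1", seq, "miR-X"), mk_mirna("loc2", seq, "miR-X")]
        )
        hits = align_insert(seq, build_index(db))
        assert {h.feature_id for h in hits} == {"loc1", "loc2"}

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_agrees_with_brute_force_oracle(self, max_mm):
        """Seed-and-verify (with its short-insert fallback) must equal the
        exhaustive Hamming scan, including mutated and random inserts."""
        db = generate_reference(
            RefConfig(n_mirna=120, n_other_ncrna=40, n_repeat=20, n_coding=10,
                      n_unannotated=10, seed=31)
        )
        idx = build_index(db, max_mismatches=max_mm)
        rng = np.random.default_rng(33)
        seqs = [rec.seq for rec in db]
        inserts = []
        for _ in range(150):
            kind = rng.integers(0, 3)
            if kind == 0:  # verbatim reference
                inserts.append(seqs[rng.integers(len(seqs))])
            elif kind == 1:  # mutated reference
                seq = list(seqs[rng.integers(len(seqs))])
                for _ in range(rng.integers(1, 3)):
                    pos = rng.integers(len(seq))
                    seq[pos] = "ACGT"[rng.integers(4)]
                inserts.append("".join(seq))
            else:  # random
                length = int(rng.integers(15, 41))
                inserts.append("".join("ACGT"[b] for b in rng.integers(0, 4, length)))
        for insert in inserts:
            got = {h.feature_id: h.n_mismatches for h in align_insert(insert, idx)}
            assert got == brute_force_hits(insert, db, max_mm), insert

    def test_hits_sorted_by_mismatch_then_id(self):
        base = "ACGTACGTACGTACGTACGT"
        mutated = "TCGTACGTACGTACGTACGT"
        db = ReferenceDB([mk_mirna("b", base), mk_mirna("a", mutated)])
        hits = align_insert(base, build_index(db, max_mismatches=1))
        assert [(h.feature_id, h.n_mismatches) for h in hits] == [("b", 0), ("a", 1)]


class TestAssignAnnotation:
    def test_no_hits_unmapped(self):
        call = assign_annotation([])
        assert call.status == "unmapped"
        assert call.rna_class is None

    def test_mature_name_collapse_is_unique(self):
        hits = [
            Hit("loc1", "miRNA", "miR-X", 0),
            Hit("loc2", "miRNA", "miR-X", 0),
        ]
        call = assign_annotation(hits)
        assert (call.status, call.rna_class, call.mature_name) == (
            "unique",
            "miRNA",
            "miR-X",
        )

    def test_minimum_mismatch_stratum_first(self):
        hits = [
            Hit("rep1", "repeat", "rep1", 0),
            Hit("mir1", "miRNA", "miR-1", 1),
        ]
        call = assign_annotation(hits)
        assert (call.status, call.rna_class) == ("unique", "repeat")

    def test_class_priority_within_stratum(self):
        hits = [
            Hit("mir1", "miRNA", "miR-1", 0),
            Hit("rep1", "repeat", "rep1", 0),
        ]
        call = assign_annotation(hits)
        assert call.rna_class == "miRNA"
        assert call.status == "multi"  # distinct features, distinct names

    def test_two_mature_names_is_multi(self):
        hits = [
            Hit("m1", "miRNA", "miR-1", 0),
            Hit("m2", "miRNA", "miR-2", 0),
        ]
        assert assign_annotation(hits).status == "multi"


class TestAnnotateLibrary:
    def test_all_unmapped(self, small_ref):
        idx = build_index(small_ref, max_mismatches=0)
        result = annotate_library(["G" * 20, "G" * 21], idx)
        assert result.n_unmapped == 2
        assert result.class_read_counts == {}

    def test_counts_invariant_to_locus_multiplicity(self):
        seq = "ACGTACGTACGTACGTACGTA"
        single = ReferenceDB([mk_mirna("loc1", seq, "miR-X")])
        double = ReferenceDB(
            [mk_mirna("loc1", seq, "miR-X"), mk_mirna("loc2", seq, "miR-X")]
        )
        reads = [seq] * 7
        for db in (single, double):
            result = annotate_library(reads, build_index(db))
            assert result.mirna_counts == {"miR-X": 7.0}

    def test_tied_mature_names_split_fractionally(self):
        seq = "ACGTACGTACGTACGTACGTA"
        db = ReferenceDB([mk_mirna("m1", seq, "miR-1"), mk_mirna("m2", seq, "miR-2")])
        result = annotate_library([seq] * 4, build_index(db))
        assert result.mirna_counts == {"miR-1": 2.0, "miR-2": 2.0}
        assert result.n_multi == 4

    def test_conservation_and_recovery_on_synthetic_library(self, blood_ref):
        cfg = LibraryConfig(n_reads=30_000, seed=41)
        reads, manifest = generate_library(blood_ref, cfg, "lib")
        survivors, _ = run_qc(reads)
        result = annotate_library(survivors, build_index(blood_ref))
        # every surviving read lands in exactly one mapping status
        assert result.n_unmapped + result.n_unique + result.n_multi == len(survivors)
        # ... and, if mapped, in exactly one class
        assert result.n_unique + result.n_multi == sum(
            result.class_read_counts.values()
        )
        # class mixture matches generator truth within 3 binomial SE
        truth = manifest.clean_class_counts()
        n_clean = sum(truth.values())
        for rna_class, true_count in truth.items():
            p = true_count / n_clean
            se = np.sqrt(p * (1 - p) / n_clean)
            observed = (
                result.n_unmapped
                if rna_class == "unmapped"
                else result.class_read_counts.get(rna_class, 0)
            ) / len(survivors)
            assert abs(observed - p) <= 3 * se + 1e-9, rna_class
        # abundance recovery: Spearman >= 0.95 on well-covered miRNAs
        true_mature = manifest.true_mature_counts
        common = [m for m, c in true_mature.items() if c >= 10]
        est = [result.mirna_counts.get(m, 0.0) for m in common]
        rho = stats.spearmanr([true_mature[m] for m in common], est).statistic
        assert rho >= 0.95
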