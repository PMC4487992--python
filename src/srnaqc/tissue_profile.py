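"""Tissue expression profiling: per-feature expression fractions, tissue-
exclusive feature sets and pairwise co-expression across tissues.

A feature is "detected in tissue T" when its count reaches the threshold in
every replicate library of T (``all_replicates``, consistent with the strict
all-libraries detection rule) or in at least one (``any_replicate``).
Expression fractions are computed on replicate-summed counts within one
annotation class, so a statement like "one miRNA accounts for 90 % of miRNA
reads in blood" is read straight off the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import pandas as pd

from .io_formats import CountMatrix
from .quantify import detected_features


def expression_fractions(counts: pd.Series | Mapping[str, float]) -> pd.Series:
    """Per-feature share of a (class-restricted) count vector, sorted
    descending; fractions sum to 1. Errors when the total is zero."""
    series = pd.Series(counts, dtype=float)
    total = series.sum()
    if total <= 0:
        raise ValueError("total count is zero; fractions undefined")
    return (series / total).sort_values(ascending=False)


def venn_partition(sets: Mapping[str, set]) -> dict[frozenset, int]:
    """Counts of every non-empty membership region of 2–4 named sets.

    Keys are frozensets of the names a region belongs to (exactly — a
    feature in blood and brain only is counted under {blood, brain}, not
    under {blood}). Region counts therefore partition the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition supports 2–4 sets")
    regions: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            )
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def exclusive_counts(sets: Mapping[str, set]) -> dict[str, int]:
    """Features found in exactly one of the named sets."""
    regions = venn_partition(sets)
    return {name: regions[frozenset([name])] for name in sets}


def coexpression(reference_set: set, other_set: set) -> tuple[int, float]:
    """Overlap of two detected-feature sets, as a count and as a percentage
    of the reference set: (|A∩B|, 100·|A∩B|/|A|)."""
    if not reference_set:
        raise ValueError("reference set is empty")
    overlap = len(reference_set & other_set)
    return overlap, 100.0 * overlap / len(reference_set)


@dataclass
class TissueProfile:
    """Detected sets, expression fractions and overlap structure per tissue."""

    rna_class: str
    threshold: float
    scope: str
    detected: dict[str, set]
    fractions: dict[str, pd.Series]
    venn: dict[frozenset, int]
    exclusive: dict[str, int]
    coexpression_table: pd.DataFrame  # tissue_a, tissue_b, overlap, pct_of_a

    def write_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (
            f"# class={self.rna_class} threshold={self.threshold} "
            f"scope={self.scope}\n"
        )
        for tissue, frac in self.fractions.items():
            path = outdir / f"fractions_{tissue}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                frac.rename("fraction").to_frame().to_csv(
                    fh, sep="\t", float_format="%.6f"
                )
        with open(outdir / "venn.tsv", "w") as fh:
            fh.write(header + "region\tcount\n")
            for region in sorted(self.venn, key=lambda r: (len(r), sorted(r))):
                fh.write("&".join(sorted(region)) + f"\t{self.venn[region]}\n")
        with open(outdir / "detected.tsv", "w") as fh:
            fh.write(header + "tissue\tn_detected\tfeatures\n")
            for tissue in sorted(self.detected):
                feats = sorted(self.detected[tissue])
                fh.write(f"{tissue}\t{len(feats)}\t{','.join(feats)}\n")
        with open(outdir / "coexpression.tsv", "w") as fh:
            fh.write(header)
            self.coexpression_table.to_csv(
                fh, sep="\t", index=False, float_format="%.1f"
            )


def profile_tissues(
    matrix: CountMatrix,
    groups: Mapping[str, str],
    rna_class: str = "miRNA",
    threshold: float = 1,
    scope: str = "all_replicates",
    reference_tissue: str | None = None,
) -> TissueProfile:
    """Profile a count matrix whose libraries are grouped into tissues.

    ``groups`` maps library id -> tissue. Co-expression is reported for every
    ordered tissue pair (or only pairs anchored at ``reference_tissue``), as
    overlap count and percent of the first tissue's detected set.
    """
    missing = [lib for lib in matrix.libraries if lib not in groups]
    if missing:
        raise ValueError(f"libraries missing a tissue group: {missing}")
    sub = matrix.subset_class(rna_class)
    rep_scope = {"all_replicates": "all_libraries", "any_replicate": "any_library"}
    if scope not in rep_scope:
        raise ValueError(f"unknown scope {scope!r}")

    tissues = sorted(set(groups[lib] for lib in matrix.libraries))
    detected: dict[str, set] = {}
    fractions: dict[str, pd.Series] = {}
    for tissue in tissues:
        libs = [lib for lib in matrix.libraries if groups[lib] == tissue]
        block = sub.counts[libs]
        detected[tissue] = detected_features(block, threshold, rep_scope[scope])
        pooled = block.sum(axis=1)
        pooled = pooled[pooled > 0]
        fractions[tissue] = expression_fractions(pooled)

    venn = venn_partition(detected) if 2 <= len(tissues) <= 4 else {}
    exclusive = exclusive_counts(detected) if venn else {}

    rows = []
    anchors = [reference_tissue] if reference_tissue else tissues
    for a in anchors:
        if a not in detected:
            raise ValueError(f"unknown reference tissue {a!r}")
        for b in tissues:
            if b == a or not detected[a]:
                continue
            overlap, pct = coexpression(detected[a], detected[b])
            rows.append(
                {"tissue_a": a, "tissue_b": b, "overlap": overlap, "pct_of_a": pct}
            )
    table = pd.DataFrame(rows, columns=["tissue_a", "tissue_b", "overlap", "pct_of_a"])
    return TissueProfile(
        rna_class=rna_class,
        threshold=threshold,
        scope=scope,
        detected=detected,
        fractions=fractions,
        venn=venn,
        exclusive=exclusive,
        coexpression_table=table,
    )
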