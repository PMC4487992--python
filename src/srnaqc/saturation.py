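"""Depth-saturation analysis: how many distinct features a given sequencing
depth can detect.

Subsampling a library of N mapped reads down to m reads is drawing without
replacement, so the subsampled count of a feature with n_i reads is
hypergeometric. The expected number of features detected at threshold t is

    E[distinct](m, t) = sum_i P( X_i >= t ),   X_i ~ Hypergeom(N, n_i, m)

which for t = 1 reduces to the classic rarefaction formula
``sum_i 1 - C(N - n_i, m) / C(N, m)`` (evaluated in log space by scipy, so it
is stable at N ~ 1e7). Monte-Carlo subsampling (multivariate hypergeometric
draws) is available alongside the analytic expectation to expose replicate
spread; halving depth repeatedly mirrors pooling twice as many samples per
sequencing lane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Depth grid, as fractions of the available depth: full, 1/2, 1/4, 1/8, 1/12
#: (the 12 M → 1 M per-million ladder used for blood-library planning).
DEFAULT_DEPTH_FACTORS = (1.0, 0.5, 0.25, 0.125, 1.0 / 12.0)

DEFAULT_THRESHOLDS = (1, 10, 20)


def _as_int_counts(counts) -> np.ndarray:
    arr = np.asarray(
        counts.to_numpy() if isinstance(counts, pd.Series) else counts, dtype=float
    )
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return np.rint(arr).astype(np.int64)


def subsample_counts(
    counts, m: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``m`` reads without replacement from a count vector.

    Multivariate hypergeometric: the result sums to ``m`` exactly and is
    reproducible given a seed. Fractional counts are rounded to integers
    before drawing.
    """
    arr = _as_int_counts(counts)
    total = int(arr.sum())
    if not 0 <= m <= total:
        raise ValueError(f"m={m} outside [0, {total}]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    return rng.multivariate_hypergeometric(arr, m, method="marginals")


def expected_distinct(counts, m: int, t: int = 1) -> float:
    """Expected number of features with subsampled count >= ``t`` after
    drawing ``m`` of the N reads without replacement."""
    if t < 1:
        raise ValueError("threshold must be >= 1")
    arr = _as_int_counts(counts)
    total = int(arr.sum())
    if not 0 <= m <= total:
        raise ValueError(f"m={m} outside [0, {total}]")
    nonzero = arr[arr > 0]
    if nonzero.size == 0 or m == 0:
        return 0.0
    # P(X_i >= t) with X_i ~ Hypergeom(M=total, n=n_i, N=m)
    tail = stats.hypergeom.sf(t - 1, total, nonzero, m)
    return float(tail.sum())


@dataclass
class SaturationCurve:
    """Expected distinct features per (depth, threshold), with optional
    Monte-Carlo replicate spread."""

    table: pd.DataFrame  # columns: depth, threshold, expected, [mc_mean, mc_sd]

    def expected(self, depth: int, threshold: int) -> float:
        row = self.table[
            (self.table.depth == depth) & (self.table.threshold == threshold)
        ]
        return float(row["expected"].iloc[0])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def saturation_curve(
    counts,
    depths: Sequence[int] | None = None,
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    reps: int = 0,
    seed: int | None = None,
) -> SaturationCurve:
    """Analytic saturation curve over a depth grid, optionally with
    Monte-Carlo replicates.

    ``depths`` defaults to the available total scaled by
    :data:`DEFAULT_DEPTH_FACTORS`. Expected counts are non-decreasing in
    depth and nested across thresholds.
    """
    arr = _as_int_counts(counts)
    total = int(arr.sum())
    if depths is None:
        depths = sorted({int(round(total * f)) for f in DEFAULT_DEPTH_FACTORS})
    depths = sorted(int(d) for d in depths)
    if depths and depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds available reads {total}")
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        mc = None
        if reps > 0:
            sub = np.stack(
                [subsample_counts(arr, depth, rng) for _ in range(reps)]
            )
        for t in thresholds:
            row = {
                "depth": depth,
                "threshold": int(t),
                "expected": expected_distinct(arr, depth, int(t)),
            }
            if reps > 0:
                distinct = (sub >= t).sum(axis=1)
                row["mc_mean"] = float(distinct.mean())
                row["mc_sd"] = float(distinct.std(ddof=1)) if reps > 1 else 0.0
            rows.append(row)
    return SaturationCurve(table=pd.DataFrame(rows))
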