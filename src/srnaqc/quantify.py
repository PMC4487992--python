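"""Multi-library count matrix, detection thresholds and normalization.

Detection follows the strict rule used for expression panels: a feature is
"detected" at threshold ``t`` when its count reaches ``t`` in *every* library
considered (an ``any_library`` scope is provided for per-tissue detection).

Normalization is the median-of-ratios size factor: for library *j*,

    s_j = median_i ( c_ij / g_i ),   g_i = ( prod_j c_ij ) ** (1/m)

with the median taken over features whose count is positive in all libraries
(the geometric mean ``g_i`` is otherwise zero). Dividing each column by its
size factor puts libraries of different depth on a common scale; no
dispersion estimation or differential testing is performed here.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


def build_count_matrix(
    per_library_counts: Mapping[str, Mapping[str, float]]
    | Iterable[tuple[str, Mapping[str, float]]],
    classes: Mapping[str, str],
    metadata: pd.DataFrame | None = None,
) -> CountMatrix:
    """Assemble per-library count vectors into one features × libraries matrix.

    The feature space is the union across libraries; a feature absent from a
    library gets count 0. Duplicate library ids are an error.
    """
    items = (
        list(per_library_counts.items())
        if isinstance(per_library_counts, Mapping)
        else list(per_library_counts)
    )
    if not items:
        raise ValueError("need at least one library")
    lib_ids = [lib for lib, _ in items]
    if len(set(lib_ids)) != len(lib_ids):
        dupes = sorted({x for x in lib_ids if lib_ids.count(x) > 1})
        raise ValueError(f"duplicate library ids: {dupes}")
    features = sorted({f for _, counts in items for f in counts})
    data = {
        lib: [float(counts.get(f, 0.0)) for f in features] for lib, counts in items
    }
    counts_df = pd.DataFrame(data, index=features, columns=lib_ids)
    class_series = pd.Series({f: classes[f] for f in features}, dtype=object)
    return CountMatrix(counts=counts_df, classes=class_series, metadata=metadata)


def detected_features(
    matrix: CountMatrix | pd.DataFrame,
    threshold: float,
    scope: str = "all_libraries",
) -> set[str]:
    """Features whose count reaches ``threshold`` in every library
    (``all_libraries``, the default) or in at least one (``any_library``)."""
    if threshold < 1:
        raise ValueError("detection threshold must be >= 1")
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if scope == "all_libraries":
        mask = (df >= threshold).all(axis=1)
    elif scope == "any_library":
        mask = (df >= threshold).any(axis=1)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return set(df.index[mask])


def size_factors(
    matrix: CountMatrix | pd.DataFrame, pseudocount: float = 0.0
) -> pd.Series:
    """Median-of-ratios size factor per library.

    Requires at least one feature with a nonzero count in every library; if
    sparsity leaves none, pass ``pseudocount`` (added to every cell for the
    factor computation only) or pre-filter the matrix.

    Factors are returned rescaled to geometric mean 1. The overall scale of
    size factors is an arbitrary gauge (only ratios between libraries
    matter); pinning it makes normalization exactly idempotent — re-deriving
    factors from a normalized matrix gives 1 for every library.
    """
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    arr = df.to_numpy(dtype=float) + pseudocount
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has a nonzero count in every library; "
            "use the pseudocount option or filter the matrix"
        )
    log_arr = np.log(arr[positive])
    log_geomean = log_arr.mean(axis=1, keepdims=True)
    log_factors = np.median(log_arr - log_geomean, axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=df.columns, name="size_factor")


def normalize(
    matrix: CountMatrix, factors: pd.Series | Mapping[str, float]
) -> CountMatrix:
    """Divide each library column by its (positive) size factor."""
    factors = pd.Series(factors).reindex(matrix.counts.columns)
    if factors.isna().any():
        missing = factors[factors.isna()].index.tolist()
        raise ValueError(f"missing size factor for libraries: {missing}")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return CountMatrix(
        counts=matrix.counts / factors,
        classes=matrix.classes,
        metadata=matrix.metadata,
    )
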