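"""Nestedness analysis: the NODF statistic and a constrained null model.

NODF ("nestedness metric based on overlap and decreasing fill") quantifies
the degree to which less diverse communities are subsets of more diverse
ones.  For every ordered pair of rows (i, j) with fill(i) > fill(j) > 0 the
paired contribution is ``100 * |ones(i) & ones(j)| / fill(j)``; pairs with
equal fills (or empty j) contribute 0.  The same is computed over column
pairs, and NODF is the sum of all contributions divided by
``r(r-1)/2 + c(c-1)/2``, giving a value in [0, 100].

Significance is assessed against an *equiprobable rows / fixed columns* null
model: each null matrix keeps every column's total fixed and scatters that
column's presences across rows uniformly at random without replacement.  The
standardized effect size is (observed - null mean) / null sd and the
one-sided upper-tail p-value uses the add-one permutation convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .tables_io import FeatureTable

__all__ = ["NestednessResult", "nodf", "nodf_ses", "collapse_and_binarize"]


@dataclass
class NestednessResult:
    nodf_observed: float
    null_mean: float
    null_sd: float
    ses: Optional[float]          # None when the null distribution is degenerate
    p_value: float
    n_iterations: int
    null_model: str
    seed: int


def _check_binary(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 rows and >=2 columns")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("matrix must be strictly 0/1; binarize explicitly first")
    return m.astype(np.int64)


def _axis_terms(m: np.ndarray) -> np.ndarray:
    """Paired NODF contributions over ordered row pairs of ``m``."""
    fills = m.sum(axis=1)
    overlap = (m @ m.T).astype(float)        # overlap[i, j] = |ones(i) & ones(j)|
    fi = fills[:, None].astype(float)
    fj = fills[None, :].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where((fi > fj) & (fj > 0), 100.0 * overlap / fj, 0.0)
    return contrib.ravel()


def nodf(binary_matrix: np.ndarray) -> float:
    """NODF in [0, 100]; direction is decided by strict fill inequality, so
    no pre-sorting of rows or columns is needed (the result is invariant to
    row and column permutations).  The paired contributions are accumulated
    with correctly rounded summation, so the value does not depend on the
    order in which pairs are visited."""
    import math

    m = _check_binary(binary_matrix)
    r, c = m.shape
    total = math.fsum(np.concatenate([_axis_terms(m), _axis_terms(m.T)]))
    denom = r * (r - 1) / 2 + c * (c - 1) / 2
    return total / denom


def _null_draw(col_sums: np.ndarray, n_rows: int, rng: np.random.Generator) -> np.ndarray:
    """One equiprobable-rows / fixed-columns matrix: column totals preserved,
    rows chosen uniformly without replacement within each column."""
    keys = rng.random((n_rows, len(col_sums)))
    order = np.argsort(keys, axis=0)
    null = np.zeros((n_rows, len(col_sums)), dtype=np.int64)
    for j, t in enumerate(col_sums):
        null[order[:t, j], j] = 1
    return null


def nodf_ses(
    binary_matrix: np.ndarray,
    n_iterations: int = 10_000,
    null_model: str = "equiprobable_rows_fixed_columns",
    seed: int = 0,
) -> NestednessResult:
    """Observed NODF with null mean/sd, SES and upper-tail p-value.

    ``p = (1 + #{null >= observed}) / (1 + n_iterations)``.  When the null
    distribution is degenerate (sd = 0), SES is reported as None while the
    p-value remains valid.
    """
    if null_model != "equiprobable_rows_fixed_columns":
        raise ValueError(f"unsupported null model {null_model!r}")
    m = _check_binary(binary_matrix)
    observed = nodf(m)
    col_sums = m.sum(axis=0)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_iterations)
    for it in range(n_iterations):
        nulls[it] = nodf(_null_draw(col_sums, m.shape[0], rng))
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    ses = (observed - null_mean) / null_sd if null_sd > 0 else None
    p = (1 + int((nulls >= observed).sum())) / (1 + n_iterations)
    return NestednessResult(
        nodf_observed=observed, null_mean=null_mean, null_sd=null_sd, ses=ses,
        p_value=p, n_iterations=n_iterations, null_model=null_model, seed=seed,
    )


def collapse_and_binarize(
    table: FeatureTable,
    hierarchy_map: pd.DataFrame,
    level: str,
) -> pd.DataFrame:
    """Sum features within each label of a hierarchy level, then threshold
    presence at > 0.

    ``hierarchy_map`` is indexed by feature id with one column per level
    (e.g. phylum..species for taxa, superclass/class/molecular formula for
    metabolites); features missing from the map or with an empty label fall
    into an ``unclassified`` bucket.  Returns a samples x labels 0/1
    DataFrame.
    """
    if level not in hierarchy_map.columns:
        raise ValueError(f"level {level!r} not in hierarchy map "
                         f"(have {list(hierarchy_map.columns)})")
    labels = hierarchy_map[level].reindex(table.feature_ids)
    labels = labels.fillna("unclassified").replace("", "unclassified")
    df = table.to_dataframe()
    collapsed = df.T.groupby(labels.values).sum().T
    return (collapsed > 0).astype(np.int64)
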