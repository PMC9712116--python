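"""Robust Aitchison ordination (RPCA).

Compositional data — sequencing counts or MS intensities — carry information
only in ratios, and are sparse.  The robust centred log-ratio transform
(rclr) log-transforms each sample and centres by the mean log of its
*nonzero* entries, leaving zeros as missing values rather than imputing
them.  A low-rank matrix completion on the observed entries then yields a
dense low-dimensional representation; the Euclidean distance between samples
in that space is the robust Aitchison distance.

The completion is alternating least squares on the observed entries with a
spectral (SVD-of-zero-filled) initialisation, in the OptSpace family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import numpy.ma as ma
import skbio

from .tables_io import FeatureTable, make_distance_matrix

logger = logging.getLogger("terraomics")

__all__ = ["Ordination", "rclr", "rpca"]


@dataclass
class Ordination:
    """SVD-style ordination: per-sample scores, per-feature loadings,
    singular values and the proportion of (completed-matrix) variance
    explained by each retained axis."""

    sample_scores: np.ndarray      # samples x k (unit-norm columns)
    feature_loadings: np.ndarray   # features x k (unit-norm columns)
    singular_values: np.ndarray    # length k
    proportion_explained: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    @property
    def k(self) -> int:
        return len(self.singular_values)

    def scaled_sample_scores(self) -> np.ndarray:
        """Scores scaled by singular values; Euclidean distances between rows
        are the robust Aitchison distances."""
        return self.sample_scores * self.singular_values[None, :]


def rclr(table: FeatureTable) -> ma.MaskedArray:
    """Robust centred log-ratio transform.

    For each sample, observed entries become ``ln(x) - mean(ln(x) over the
    sample's nonzero entries)``; zeros are masked (missing), not zero.
    Scale-invariant per sample: multiplying a sample by any c > 0 leaves its
    rclr row unchanged.
    """
    x = np.asarray(table.values, dtype=float)
    nz = x > 0
    empty = ~nz.any(axis=1)
    if empty.any():
        bad = [table.sample_ids[i] for i in np.where(empty)[0]]
        raise ValueError(f"sample(s) with no nonzero entries: {bad}")
    with np.errstate(divide="ignore"):
        logs = np.where(nz, np.log(x, where=nz, out=np.full_like(x, np.nan)), np.nan)
    row_mean = np.nanmean(logs, axis=1, keepdims=True)
    out = ma.masked_invalid(logs - row_mean)
    return out


def _als_complete(obs: ma.MaskedArray, rank: int, max_iter: int, tol: float,
                  seed: int) -> np.ndarray:
    """Rank-`rank` completion of the observed entries by alternating least
    squares, spectral initialisation from the zero-filled matrix."""
    mask = ~obs.mask  # True where observed
    x = obs.filled(0.0)
    n, m = x.shape
    # spectral init
    u0, s0, vt0 = np.linalg.svd(x, full_matrices=False)
    W = u0[:, :rank] * np.sqrt(s0[:rank])[None, :]
    H = (vt0[:rank, :].T) * np.sqrt(s0[:rank])[None, :]
    rng = np.random.default_rng(seed)
    W = W + 1e-8 * rng.standard_normal(W.shape)  # break exact degeneracies
    ridge = 1e-9 * np.eye(rank)
    obs_norm = float((x[mask] ** 2).sum())

    prev = np.inf
    for it in range(max_iter):
        for i in range(n):  # update W rows
            cols = mask[i]
            Hc = H[cols]
            W[i] = np.linalg.solve(Hc.T @ Hc + ridge, Hc.T @ x[i, cols])
        for j in range(m):  # update H rows
            rows = mask[:, j]
            Wr = W[rows]
            H[j] = np.linalg.solve(Wr.T @ Wr + ridge, Wr.T @ x[rows, j])
        resid = (W @ H.T - x)[mask]
        obj = float(resid @ resid)
        delta = abs(prev - obj) / max(obj, 1e-30)
        if obj <= 1e-15 * max(obs_norm, 1e-30) or delta < tol:
            return W @ H.T
        prev = obj
    raise RuntimeError(
        f"matrix completion did not converge in {max_iter} iterations "
        f"(last relative objective change {delta:.3e})"
    )


def rpca(
    table: FeatureTable,
    rank: int = 3,
    min_sample_features: int = 500,
    min_feature_prevalence: float = 0.10,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int = 0,
) -> tuple[Ordination, skbio.DistanceMatrix]:
    """Robust Aitchison PCA with the standard sparsity filters.

    Samples with fewer than ``min_sample_features`` nonzero features and
    features present in fewer than ``min_feature_prevalence`` of samples are
    excluded before the rclr transform; the rclr matrix is completed at the
    requested rank, double-centred, and decomposed by SVD.  The robust
    Aitchison distance is the Euclidean distance between rows of
    ``sample_scores * singular_values``.
    """
    x = table.values
    sample_keep = (x > 0).sum(axis=1) >= min_sample_features
    sub = x[sample_keep]
    if sub.shape[0] == 0:
        raise ValueError("no samples pass the min_sample_features filter")
    feat_keep = (sub > 0).mean(axis=0) >= min_feature_prevalence
    sub = sub[:, feat_keep]
    sample_ids = [s for s, k in zip(table.sample_ids, sample_keep) if k]
    feature_ids = [f for f, k in zip(table.feature_ids, feat_keep) if k]
    if sub.shape[0] < rank + 1 or sub.shape[1] < rank + 1:
        raise ValueError(
            f"after filtering, shape {sub.shape} is too small for rank {rank}"
        )
    filtered = FeatureTable(sub, sample_ids, feature_ids, table.kind)
    observed = rclr(filtered)
    completed = _als_complete(observed, rank=rank, max_iter=max_iter, tol=tol, seed=seed)
    # double-centre: remove sample and feature means (grand mean added back)
    centred = (completed
               - completed.mean(axis=1, keepdims=True)
               - completed.mean(axis=0, keepdims=True)
               + completed.mean())
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # deterministic sign: largest-magnitude loading positive per axis
    for a in range(rank):
        pivot = np.argmax(np.abs(vt[a]))
        if vt[a, pivot] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    total = (centred ** 2).sum()
    prop = (s ** 2) / total if total > 0 else np.zeros(rank)
    ord_res = Ordination(
        sample_scores=u,
        feature_loadings=vt.T,
        singular_values=s,
        proportion_explained=prop,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
    )
    coords = ord_res.scaled_sample_scores()
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    return ord_res, make_distance_matrix(dist, sample_ids)
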