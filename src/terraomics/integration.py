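"""Multi-omics synthesis of the co-occurrence, differential and ordination
layers.

The three per-metabolite summaries — loadings on the co-occurrence PCs,
per-environment differentials (log fold changes) and global-ordination
loadings (plus their overall magnitude) — are joined on the common
metabolite set and cross-correlated (Spearman, BH-adjusted over the whole
grid).  A focal/reference pair of metabolite groups is then selected from a
chosen (differential column, co-occurrence axis) plane, and validated by
per-sample log-ratios — of the metabolites themselves, and of their top
co-occurring microbes — compared between the focal environment and all
others with Welch t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community_stats import TestResult, bh_adjust, log_ratio, two_group_ttest
from .compositional_ordination import Ordination
from .cooccurrence_model import CooccurrenceModel, top_cooccurring
from .differential_ranking import DifferentialMatrix
from .tables_io import FeatureTable, SampleMetadata

logger = logging.getLogger("terraomics")

__all__ = ["IntegrationReport", "overall_magnitude", "correlate_layers",
           "select_groups", "validate_groups"]


@dataclass
class IntegrationReport:
    rho: Optional[pd.DataFrame] = None            # PCs x layer columns
    p_adjusted: Optional[pd.DataFrame] = None
    p_raw: Optional[pd.DataFrame] = None
    n_joined: Optional[int] = None
    focal_ids: list[str] = field(default_factory=list)
    reference_ids: list[str] = field(default_factory=list)
    metabolite_log_ratio: Optional[pd.Series] = None
    microbe_log_ratio: Optional[pd.Series] = None
    metabolite_test: Optional[TestResult] = None
    microbe_test: Optional[TestResult] = None


def overall_magnitude(ordination: Ordination, n_axes: int = 3) -> pd.Series:
    """Euclidean norm of each feature's loadings over the first ``n_axes``
    ordination axes — a single 'importance' score per feature, invariant to
    axis sign flips."""
    if n_axes > ordination.k:
        raise ValueError(f"n_axes={n_axes} exceeds available axes ({ordination.k})")
    mags = np.linalg.norm(ordination.feature_loadings[:, :n_axes], axis=1)
    return pd.Series(mags, index=ordination.feature_ids, name="overall_magnitude")


def correlate_layers(
    metabolite_pcs: pd.DataFrame,
    differentials: DifferentialMatrix,
    global_loadings: pd.DataFrame,
    magnitude: pd.Series,
    min_join: int = 10,
) -> IntegrationReport:
    """Spearman rho between every co-occurrence PC and every layer column.

    Layer columns are the per-environment differentials, the global
    ordination axes and the overall magnitude.  Inputs are inner-joined on
    metabolite id; BH adjustment spans the full rho grid (one family).
    """
    layers = pd.concat(
        [differentials.B, global_loadings, magnitude.rename("overall_magnitude")],
        axis=1, join="inner")
    joined = metabolite_pcs.join(layers, how="inner").dropna()
    n = len(joined)
    if n < min_join:
        raise ValueError(f"only {n} metabolites shared across layers (< {min_join})")
    pcs = metabolite_pcs.columns
    cols = layers.columns
    rho = pd.DataFrame(index=pcs, columns=cols, dtype=float)
    praw = pd.DataFrame(index=pcs, columns=cols, dtype=float)
    for pc in pcs:
        for col in cols:
            r, p = stats.spearmanr(joined[pc], joined[col])
            rho.loc[pc, col] = float(r)
            praw.loc[pc, col] = float(p)
    flat = bh_adjust(praw.values.ravel())
    padj = pd.DataFrame(flat.reshape(praw.shape), index=pcs, columns=cols)
    return IntegrationReport(rho=rho, p_adjusted=padj, p_raw=praw, n_joined=n)


def select_groups(
    pc_scores: pd.Series,
    lfc_column: pd.Series,
    lfc_quantile: float = 0.9,
    pc_window: tuple[float, float] | None = None,
) -> tuple[list[str], list[str]]:
    """Reproducible focal/reference metabolite selection.

    focal = metabolites above the ``lfc_quantile`` of the differential column
    *and* inside ``pc_window`` on the co-occurrence axis (co-occurrence
    coherent); reference = the mirrored selection below the ``1 -
    lfc_quantile`` quantile and outside/below the window's mirror.  With no
    window, selection is by differential quantile alone.  Deterministic.
    """
    if not (0.5 < lfc_quantile < 1.0):
        raise ValueError("lfc_quantile must be in (0.5, 1)")
    joined = pd.DataFrame({"pc": pc_scores, "lfc": lfc_column}).dropna()
    hi = joined["lfc"].quantile(lfc_quantile)
    lo = joined["lfc"].quantile(1.0 - lfc_quantile)
    focal = joined[joined["lfc"] > hi]
    reference = joined[joined["lfc"] < lo]
    if pc_window is not None:
        w_lo, w_hi = pc_window
        focal = focal[(focal["pc"] >= w_lo) & (focal["pc"] <= w_hi)]
        reference = reference[(reference["pc"] >= -w_hi) & (reference["pc"] <= -w_lo)]
    focal_ids = sorted(focal.index)
    reference_ids = sorted(set(reference.index) - set(focal_ids))
    if not focal_ids or not reference_ids:
        raise ValueError(
            "empty focal or reference selection; widen pc_window or lower "
            "lfc_quantile"
        )
    return focal_ids, reference_ids


def validate_groups(
    metabolite_table: FeatureTable,
    microbe_table: FeatureTable,
    model: CooccurrenceModel,
    metadata: SampleMetadata,
    focal: Sequence[str],
    reference: Sequence[str],
    focal_environment: str,
    k: int = 10,
    fraction: float | None = None,
) -> IntegrationReport:
    """Log-ratio validation of a focal/reference metabolite pair.

    Computes (1) the per-sample log-ratio of focal over reference metabolite
    intensities and (2) the log-ratio of the top ``k`` (or top ``fraction``)
    co-occurring microbes of the focal set over those of the reference set;
    each is compared between ``focal_environment`` and all other
    environments with a Welch t-test.
    """
    focal = list(focal)
    reference = list(reference)
    if not focal or not reference:
        raise ValueError("focal and reference must be nonempty")
    if set(focal) & set(reference):
        raise ValueError("focal and reference groups overlap")

    met_lr = log_ratio(metabolite_table, focal, reference)

    top_focal = list(top_cooccurring(model, focal, k=k, fraction=fraction).index)
    top_ref = list(top_cooccurring(model, reference, k=k, fraction=fraction).index)
    shared = set(top_focal) & set(top_ref)
    top_focal = [m for m in top_focal if m not in shared]
    top_ref = [m for m in top_ref if m not in shared]
    if not top_focal or not top_ref:
        raise ValueError("top co-occurring microbe sets collapse onto each "
                         "other; increase k or refine the groups")
    mic_lr = log_ratio(microbe_table, top_focal, top_ref)

    env = metadata.frame["empo_4"]
    met_mask = env.reindex(met_lr.index) == focal_environment
    mic_mask = env.reindex(mic_lr.index) == focal_environment
    met_test = two_group_ttest(met_lr, met_mask)
    mic_test = two_group_ttest(mic_lr, mic_mask)
    return IntegrationReport(
        focal_ids=focal, reference_ids=reference,
        metabolite_log_ratio=met_lr, microbe_log_ratio=mic_lr,
        metabolite_test=met_test, microbe_test=mic_test,
    )
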