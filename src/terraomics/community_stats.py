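"""Alpha/beta diversity and the permutation/correlation test battery.

Phylogenetic metrics share one machinery: a branch x tip incidence built
from the rooted tree.  With ``p(branch)`` the summed relative abundance of
the tips descending from a branch,

* Faith's PD       = total length of branches subtending >=1 observed tip
                     (path to the root included),
* weighted Faith's PD = sum over branches of length x mean relative
                     abundance of descendant tips,
* weighted UniFrac = sum over branches of length x |p_A - p_B|.

Permutation tests (PERMANOVA, Mantel) use the add-one convention
``p = (1 + #{perm >= obs}) / (1 + n_permutations)`` and take explicit seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import skbio
from scipy import stats

from .tables_io import FeatureTable, make_distance_matrix

logger = logging.getLogger("terraomics")

__all__ = [
    "TestResult", "alpha_diversity", "weighted_unifrac", "permanova",
    "mantel", "multilevel_spearman", "kruskal_wallis", "log_ratio",
    "two_group_ttest", "bh_adjust",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n_permutations: Optional[int] = None
    df: Optional[float] = None
    adjusted_p: Optional[float] = None
    extra: Optional[dict] = None


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one declared test family."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Phylogenetic machinery
# ---------------------------------------------------------------------------

def _branch_incidence(tree: skbio.TreeNode, tip_order: list[str]):
    """(lengths, incidence) where incidence[b, t] = 1 if tip t descends from
    branch b.  Every non-root node contributes its branch."""
    tip_pos = {name: i for i, name in enumerate(tip_order)}
    branches = [n for n in tree.traverse(include_self=False)]
    lengths = np.array([float(n.length or 0.0) for n in branches])
    inc = np.zeros((len(branches), len(tip_order)), dtype=bool)
    for bi, node in enumerate(branches):
        for tip in node.tips(include_self=True):
            if tip.name in tip_pos:
                inc[bi, tip_pos[tip.name]] = True
    return lengths, inc


def _prepare_tree(table: FeatureTable, tree: skbio.TreeNode):
    tips = {t.name for t in tree.tips()}
    missing = [f for f in table.feature_ids if f not in tips]
    if missing:
        raise ValueError(f"tree is missing tips for features: {missing[:5]}...")
    extra = tips - set(table.feature_ids)
    work = tree
    if extra:
        work = tree.shear(set(table.feature_ids))
        for node in work.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    return _branch_incidence(work, table.feature_ids)


def alpha_diversity(
    table: FeatureTable,
    metric: str,
    tree: Optional[skbio.TreeNode] = None,
) -> pd.Series:
    """Per-sample alpha diversity.

    metric : {"richness", "faith_pd", "weighted_faith_pd"}
        Richness counts features with abundance > 0.  Both PD metrics
        require a rooted tree covering the table's features (extra tips are
        pruned); Faith's PD includes the path to the root.
    """
    if metric == "richness":
        vals = (table.values > 0).sum(axis=1).astype(float)
        return pd.Series(vals, index=table.sample_ids, name="richness")
    if metric not in ("faith_pd", "weighted_faith_pd"):
        raise ValueError(f"unknown metric {metric!r}")
    if tree is None:
        raise ValueError(f"{metric} requires a phylogeny")
    lengths, inc = _prepare_tree(table, tree)
    x = table.values
    out = np.zeros(table.n_samples)
    for n in range(table.n_samples):
        present = x[n] > 0
        if metric == "faith_pd":
            covered = inc[:, present].any(axis=1)
            out[n] = float(lengths[covered].sum())
        else:
            total = x[n].sum()
            if total <= 0:
                out[n] = 0.0
                continue
            rel = x[n] / total
            n_desc = inc.sum(axis=1)
            mean_rel = (inc @ rel) / np.maximum(n_desc, 1)
            out[n] = float((lengths * mean_rel).sum())
    return pd.Series(out, index=table.sample_ids, name=metric)


def weighted_unifrac(table: FeatureTable, tree: skbio.TreeNode) -> skbio.DistanceMatrix:
    """Weighted UniFrac distances between all sample pairs."""
    totals = table.values.sum(axis=1)
    if np.any(totals <= 0):
        bad = [table.sample_ids[i] for i in np.where(totals <= 0)[0]]
        raise ValueError(f"sample(s) with zero total: {bad}")
    lengths, inc = _prepare_tree(table, tree)
    rel = table.values / totals[:, None]
    branch_mass = rel @ inc.T.astype(float)       # samples x branches
    diff = np.abs(branch_mass[:, None, :] - branch_mass[None, :, :])
    dist = diff @ lengths
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    return make_distance_matrix(dist, table.sample_ids)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.where(codes == g)[0]
        if len(members) < 2:
            continue
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dm: skbio.DistanceMatrix,
    grouping: Sequence[str] | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> TestResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F statistic compares between- to within-group dispersion of
    squared distances; significance comes from permuting group labels.
    """
    if isinstance(grouping, pd.Series):
        grouping = grouping.loc[list(dm.ids)]
        labels = np.asarray(grouping.values)
    else:
        labels = np.asarray(list(grouping))
    if len(labels) != len(dm.ids):
        raise ValueError("grouping length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValueError("need >=2 groups")
    if k == n:
        raise ValueError("every sample is its own group (singleton grouping)")
    d2 = dm.data ** 2
    f_obs = _pseudo_f(d2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _pseudo_f(d2, codes[perm], k) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return TestResult(name="PERMANOVA pseudo-F", statistic=float(f_obs),
                      p_value=p, n_permutations=n_permutations,
                      extra={"n_groups": k, "n_samples": n, "seed": seed})


def mantel(
    dm_a: skbio.DistanceMatrix,
    dm_b: skbio.DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> TestResult:
    """Mantel test with Spearman correlation over upper-triangle distances.

    Matrices are aligned on their shared samples first; one matrix's sample
    labels are permuted; the p-value is two-sided (|rho_perm| >= |rho_obs|).
    """
    shared = [s for s in dm_a.ids if s in set(dm_b.ids)]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared samples, have {len(shared)}")
    a = dm_a.filter(shared).data
    b = dm_b.filter(shared).data
    n = len(shared)
    iu = np.triu_indices(n, k=1)
    ranks_a = stats.rankdata(a[iu])
    rho_obs = float(stats.spearmanr(a[iu], b[iu]).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        rho = float(stats.spearmanr(ranks_a, bp[iu]).statistic)
        if abs(rho) >= abs(rho_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return TestResult(name="Mantel Spearman rho", statistic=rho_obs, p_value=p,
                      n_permutations=n_permutations,
                      extra={"n_samples": n, "seed": seed})


# ---------------------------------------------------------------------------
# Correlation / rank tests
# ---------------------------------------------------------------------------

def multilevel_spearman(
    x: pd.Series,
    y: pd.Series,
    group: pd.Series,
    bh_family: Optional[Sequence[float]] = None,
) -> TestResult:
    """Spearman correlation with a group (study) random-effect adjustment.

    Within every group of size >= 2, x and y are ranked and the ranks centred
    at the group mean; the correlation is then computed on the pooled centred
    ranks.  This removes group-level location shifts (a rank analogue of a
    random intercept).  Groups of size 1 contribute nothing.  If
    ``bh_family`` (the other p-values of the declared family) is given, the
    adjusted p for this test under Benjamini-Hochberg across the family is
    reported.
    """
    df = pd.DataFrame({"x": x, "y": y, "g": group}).dropna()
    cx, cy = [], []
    n_used = 0
    for _, sub in df.groupby("g"):
        if len(sub) < 2:
            continue
        rx = stats.rankdata(sub["x"])
        ry = stats.rankdata(sub["y"])
        cx.append(rx - rx.mean())
        cy.append(ry - ry.mean())
        n_used += len(sub)
    if not cx:
        raise ValueError("all groups have size 1; correlation undefined")
    cx = np.concatenate(cx)
    cy = np.concatenate(cy)
    denom = np.sqrt((cx ** 2).sum() * (cy ** 2).sum())
    rho = float((cx * cy).sum() / denom) if denom > 0 else 0.0
    n_eff = len(cx)
    if abs(rho) >= 1.0:
        p = 0.0 if n_eff > 2 else 1.0
    else:
        t = rho * np.sqrt(max(n_eff - 2, 1) / (1 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), df=max(n_eff - 2, 1)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    adjusted = None
    if bh_family is not None:
        fam = list(bh_family) + [p]
        adjusted = float(bh_adjust(fam)[-1])
    return TestResult(name="multilevel Spearman rho", statistic=rho, p_value=p,
                      df=float(n_eff - 2), adjusted_p=adjusted,
                      extra={"n_samples_used": n_used})


def kruskal_wallis(values: pd.Series, groups: pd.Series) -> TestResult:
    """Kruskal-Wallis H (chi-squared) across groups, with tie correction."""
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    arrays = [sub["v"].values for _, sub in df.groupby("g")]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >=2 nonempty groups")
    if df["v"].nunique() == 1:
        return TestResult(name="Kruskal-Wallis H", statistic=0.0, p_value=1.0,
                          df=float(len(arrays) - 1))
    h, p = stats.kruskal(*arrays)
    return TestResult(name="Kruskal-Wallis H", statistic=float(h),
                      p_value=float(p), df=float(len(arrays) - 1))


def log_ratio(
    table: FeatureTable,
    numerator_ids: Sequence[str],
    denominator_ids: Sequence[str],
) -> pd.Series:
    """Per-sample ``ln(sum(numerator) / sum(denominator))``.

    Samples with a zero sum on either side are dropped (the count is
    logged).  The two id sets must be nonempty and disjoint.
    """
    num = list(numerator_ids)
    den = list(denominator_ids)
    if not num or not den:
        raise ValueError("numerator and denominator sets must be nonempty")
    overlap = set(num) & set(den)
    if overlap:
        raise ValueError(f"numerator/denominator overlap: {sorted(overlap)}")
    df = table.to_dataframe()
    missing = [f for f in num + den if f not in df.columns]
    if missing:
        raise ValueError(f"features not in table: {missing[:5]}...")
    ns = df[num].sum(axis=1)
    ds = df[den].sum(axis=1)
    ok = (ns > 0) & (ds > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("log_ratio: dropped %d sample(s) with zero numerator or "
                    "denominator sum", n_dropped)
    return pd.Series(np.log(ns[ok] / ds[ok]), index=df.index[ok], name="log_ratio")


def two_group_ttest(values: pd.Series, focal_mask: pd.Series) -> TestResult:
    """Welch (unequal-variance) two-sided t-test of focal vs other samples."""
    v = values.dropna()
    mask = focal_mask.reindex(v.index).astype(bool)
    a, b = v[mask].values, v[~mask].values
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >=2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return TestResult(name="Welch t", statistic=0.0, p_value=1.0,
                              extra={"mean_shift": 0.0})
        raise ValueError("both groups are constant with different means; "
                         "t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # identical constant groups handled above; zero-variance halves
        t, p = 0.0, 1.0
    return TestResult(name="Welch t", statistic=float(t), p_value=float(p),
                      extra={"mean_shift": float(a.mean() - b.mean()),
                             "n_focal": len(a), "n_other": len(b)})
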