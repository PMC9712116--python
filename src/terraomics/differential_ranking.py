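"""Multinomial differential ranking of features across environments.

Feature abundances are modelled as multinomial draws whose log-proportions
shift additively by environment:

    y_n ~ Multinomial(softmax(b0 + B[:, env(n)]))

with a one-hot environment design (reference level dropped) and a Gaussian
prior on the environment coefficients.  Because only ratios are observed, the
coefficients are identified up to an additive constant per environment
(across features) and, through the choice of reference, up to a per-feature
offset shared by all environments.  Both gauges are fixed after fitting:
coefficients are centred per feature across environments (which makes the
feature *ranks* within an environment invariant to the choice of reference)
and then per environment across features.  The resulting matrix of
"differentials" orders features by their association with each environment;
only relative orderings are interpretable.

Intensities are handled identically to counts after per-sample closure:
each sample is normalised to proportions and given a fixed total weight
(``closure_depth``), so the fit depends on each sample's composition only —
multiplying any sample by a positive constant leaves the differentials
unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import spearmanr

from .tables_io import FeatureTable, SampleMetadata

logger = logging.getLogger("terraomics")

__all__ = ["DifferentialMatrix", "fit_differentials", "reference_consistency",
           "top_differentials"]


@dataclass
class DifferentialMatrix:
    """Per-feature, per-environment log-fold-change estimates (centred)."""

    B: pd.DataFrame               # features x environments
    reference_environment: str
    training_fraction: float
    hyperparameters: dict = field(default_factory=dict)

    @property
    def environments(self) -> list[str]:
        return list(self.B.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.B.index)


def _stratified_split(envs: pd.Series, training_fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Boolean train mask, stratified by environment."""
    train = np.zeros(len(envs), dtype=bool)
    for env in envs.unique():
        idx = np.where(envs.values == env)[0]
        n_train = int(round(training_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx))
        chosen = rng.choice(idx, size=n_train, replace=False)
        train[chosen] = True
    return train


def fit_differentials(
    table: FeatureTable,
    metadata: SampleMetadata,
    reference_env: str,
    prior_sd: float = 0.5,
    epochs: int = 10_000,
    learning_rate: float = 1e-5,
    batch_size: int = 400,
    training_fraction: float = 0.8,
    min_env_size: int = 10,
    closure_depth: float = 1000.0,
    seed: int = 0,
) -> DifferentialMatrix:
    """Fit the multinomial environment model and return centred differentials.

    Environments with fewer than ``min_env_size`` samples are excluded before
    fitting.  A stratified ``training_fraction`` split by environment selects
    the training samples.  The penalised likelihood is maximised to
    convergence with a full-batch quasi-Newton optimiser (``epochs`` caps the
    iteration count; ``learning_rate`` and ``batch_size`` are recorded for
    provenance but the optimiser is deterministic and step-size free).
    """
    md = metadata.frame
    real = [s for s in table.sample_ids
            if s in md.index and md.loc[s, "control_role"] == "none"]
    envs_all = md.loc[real, "empo_4"]
    env_counts = envs_all.value_counts()
    kept_envs = sorted(env_counts.index[env_counts >= min_env_size])
    if len(kept_envs) < 2:
        raise ValueError(
            f"need >=2 environments with >= {min_env_size} samples; "
            f"have {kept_envs}"
        )
    if reference_env not in kept_envs:
        raise ValueError(f"reference environment {reference_env!r} not among "
                         f"usable environments {kept_envs}")
    samples = [s for s in real if envs_all[s] in kept_envs]
    envs = envs_all.loc[samples]

    rng = np.random.default_rng(seed)
    train_mask = _stratified_split(envs, training_fraction, rng)
    if not train_mask.any():
        raise ValueError("empty training set")
    for env in kept_envs:
        if not train_mask[(envs.values == env)].any():
            raise ValueError(f"environment {env!r} has no training samples")

    sub = table.select_samples(samples)
    x = sub.values
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        bad = [samples[i] for i in np.where(totals <= 0)[0]]
        raise ValueError(f"sample(s) with zero total abundance: {bad}")
    props = x / totals[:, None]
    weights = props * closure_depth          # per-sample composition, fixed mass

    env_order = [reference_env] + [e for e in kept_envs if e != reference_env]
    J, E = sub.n_features, len(env_order)
    # aggregate training weights per environment (one-hot design => shared logits)
    W = np.zeros((E, J))
    T = np.zeros(E)
    for e, env in enumerate(env_order):
        rows = train_mask & (envs.values == env)
        W[e] = weights[rows].sum(axis=0)
        T[e] = closure_depth * rows.sum()

    lam = 1.0 / (2.0 * prior_sd ** 2)

    def objective(params: np.ndarray):
        b0 = params[:J]
        Braw = params[J:].reshape(J, E - 1)
        logits = np.tile(b0[None, :], (E, 1))
        logits[1:] += Braw.T
        lse = logsumexp(logits, axis=1)
        ll = float((W * logits).sum() - (T * lse).sum())
        p = np.exp(logits - lse[:, None])
        g_eta = -(W - T[:, None] * p)        # E x J
        loss = -ll + lam * float((Braw ** 2).sum()) + 1e-6 * float(b0 @ b0)
        g_b0 = g_eta.sum(axis=0) + 2e-6 * b0
        g_B = g_eta[1:].T + 2.0 * lam * Braw
        return loss, np.concatenate([g_b0, g_B.ravel()])

    x0 = np.zeros(J * E)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": int(epochs), "ftol": 1e-12, "gtol": 1e-9})
    b0 = res.x[:J]
    Braw = res.x[J:].reshape(J, E - 1)
    B_full = np.zeros((J, E))
    B_full[:, 1:] = Braw
    # gauge fixing: per-feature centring across environments (reference-robust
    # ranks), then per-environment centring across features
    B_full = B_full - B_full.mean(axis=1, keepdims=True)
    B_full = B_full - B_full.mean(axis=0, keepdims=True)
    B = pd.DataFrame(B_full, index=sub.feature_ids, columns=env_order)
    B = B[sorted(env_order)]
    return DifferentialMatrix(
        B=B,
        reference_environment=reference_env,
        training_fraction=training_fraction,
        hyperparameters={
            "prior_sd": prior_sd, "epochs": epochs,
            "learning_rate": learning_rate, "batch_size": batch_size,
            "min_env_size": min_env_size, "closure_depth": closure_depth,
            "seed": seed, "converged": bool(res.success),
            "n_iterations": int(res.nit),
        },
    )


def reference_consistency(
    table: FeatureTable,
    metadata: SampleMetadata,
    ref_a: str,
    ref_b: str,
    seed: int = 0,
    **fit_kwargs,
) -> pd.Series:
    """Per-environment Spearman rho between differentials fit under two
    different reference environments (same split seed)."""
    da = fit_differentials(table, metadata, ref_a, seed=seed, **fit_kwargs)
    db = fit_differentials(table, metadata, ref_b, seed=seed, **fit_kwargs)
    shared = [e for e in da.environments if e in db.environments]
    rhos = {}
    for env in shared:
        rho, _ = spearmanr(da.B[env], db.B[env])
        rhos[env] = float(rho)
    return pd.Series(rhos, name="spearman_rho")


def top_differentials(diff: DifferentialMatrix, environment: str, k: int = 10) -> list[str]:
    """The ``k`` features with the largest differential in ``environment``;
    ties broken lexicographically by feature id."""
    if environment not in diff.B.columns:
        raise ValueError(f"unknown environment {environment!r}; "
                         f"have {list(diff.B.columns)}")
    col = diff.B[environment]
    order = sorted(col.index, key=lambda f: (-col[f], f))
    return order[: min(k, len(order))]
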