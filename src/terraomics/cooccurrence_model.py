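"""Microbe-metabolite co-occurrence factor model.

Metabolite abundances are modelled conditionally on microbial composition:
each microbe i carries a conditional distribution over metabolites,
``softmax_j(U[i] . V[j] + b[j])``, and a sample's expected metabolite
proportions are the mixture of those distributions weighted by the sample's
microbial relative abundances q_n:

    p_n(j) = sum_i q_ni * softmax_j(U[i] . V[j] + b[j])

The latent inner products ``L[i, j] = U[i] . V[j] + b[j]`` are the log
conditional probabilities up to a per-microbe constant — the "co-occurrence
strength" between microbe i and metabolite j.  U, V carry Gaussian priors.
The fit maximises the multinomial log-likelihood of the metabolite table on
an environment-balanced training split; model quality is summarised by a
cross-validated pseudo-Q^2 against a pooled-proportion baseline.

This implementation uses the deterministic expectation form of the mixture
(every microbe contributes with weight q_ni at each step) rather than
sampling microbes stochastically per gradient step, which makes the fit
reproducible bit-for-bit under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .tables_io import FeatureTable, SampleMetadata

logger = logging.getLogger("terraomics")

__all__ = ["CooccurrenceModel", "fit_cooccurrence", "pseudo_q2",
           "cooccurrence_ordination", "top_cooccurring"]


@dataclass
class CooccurrenceModel:
    U: pd.DataFrame                # microbes x k
    V: pd.DataFrame                # metabolites x k
    b: pd.Series                   # metabolite biases
    k: int
    train_samples: list[str] = field(default_factory=list)
    test_samples: list[str] = field(default_factory=list)
    train_metabolite_proportions: np.ndarray | None = None  # pooled baseline
    hyperparameters: dict = field(default_factory=dict)

    @property
    def microbe_ids(self) -> list[str]:
        return list(self.U.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.V.index)

    def log_conditional(self, centred: bool = False) -> pd.DataFrame:
        """L[i, j] = U[i].V[j] + b[j]; with ``centred=True`` the per-microbe
        softmax constant is removed (row log-sum-exp subtracted), giving true
        log conditional probabilities."""
        L = self.U.values @ self.V.values.T + self.b.values[None, :]
        if centred:
            from scipy.special import logsumexp

            L = L - logsumexp(L, axis=1, keepdims=True)
        return pd.DataFrame(L, index=self.microbe_ids, columns=self.metabolite_ids)

    def predict_proportions(self, microbe_table: FeatureTable) -> pd.DataFrame:
        """p_n(j) for each sample of ``microbe_table`` (rows sum to 1)."""
        sub = microbe_table.select_features(self.microbe_ids)
        q = sub.values / sub.values.sum(axis=1, keepdims=True)
        eta = self.U.values @ self.V.values.T + self.b.values[None, :]
        s = np.exp(eta - eta.max(axis=1, keepdims=True))
        s /= s.sum(axis=1, keepdims=True)
        p = q @ s
        return pd.DataFrame(p, index=sub.sample_ids, columns=self.metabolite_ids)


def _balanced_split(envs: pd.Series, training_fraction: float,
                    rng: np.random.Generator) -> np.ndarray:
    train = np.zeros(len(envs), dtype=bool)
    for env in envs.unique():
        idx = np.where(envs.values == env)[0]
        n_train = min(max(int(round(training_fraction * len(idx))), 1), len(idx))
        train[rng.choice(idx, size=n_train, replace=False)] = True
    return train


def fit_cooccurrence(
    microbe_table: FeatureTable,
    metabolite_table: FeatureTable,
    metadata: SampleMetadata | None = None,
    latent_dim: int = 10,
    min_feature_count: int = 10,
    epochs: int = 200,
    batch_size: int = 165,
    learning_rate: float = 1e-5,
    training_fraction: float = 0.8,
    prior_sd: float = 1.0,
    seed: int = 0,
) -> CooccurrenceModel:
    """Fit the conditional metabolite model on an environment-balanced split.

    Both tables must be sample-aligned.  Features present in fewer than
    ``min_feature_count`` samples are removed from each table before
    fitting.  ``epochs`` caps the optimiser iterations; ``batch_size`` and
    ``learning_rate`` are recorded for provenance (the optimiser is
    full-batch and step-size free).
    """
    if microbe_table.sample_ids != metabolite_table.sample_ids:
        raise ValueError("tables must be sample-aligned (same ids, same order)")
    n_samples = microbe_table.n_samples
    if n_samples < latent_dim + 1:
        raise ValueError(f"{n_samples} samples < latent_dim+1 = {latent_dim + 1}")

    def prevalence_filter(t: FeatureTable) -> FeatureTable:
        keep = (t.values > 0).sum(axis=0) >= min_feature_count
        ids = [f for f, k in zip(t.feature_ids, keep) if k]
        if not ids:
            raise ValueError("no features pass the min_feature_count filter")
        return t.select_features(ids)

    mic = prevalence_filter(microbe_table)
    met = prevalence_filter(metabolite_table)

    rng = np.random.default_rng(seed)
    if metadata is not None:
        envs = metadata.frame.loc[mic.sample_ids, "empo_4"]
    else:
        envs = pd.Series("all", index=mic.sample_ids)
    train_mask = _balanced_split(envs, training_fraction, rng)

    q_all = mic.values / np.maximum(mic.values.sum(axis=1, keepdims=True), 1e-12)
    Y_all = met.values
    Q, Y = q_all[train_mask], Y_all[train_mask]

    M, J, K = mic.n_features, met.n_features, latent_dim
    lam = 1.0 / (2.0 * prior_sd ** 2)
    scale = 1.0 / max(Y.sum(), 1.0)          # normalise loss for optimizer ftol

    def unpack(params):
        U = params[: M * K].reshape(M, K)
        V = params[M * K: M * K + J * K].reshape(J, K)
        b = params[M * K + J * K:]
        return U, V, b

    def objective(params):
        U, V, b = unpack(params)
        eta = U @ V.T + b[None, :]                        # M x J
        eta -= eta.max(axis=1, keepdims=True)
        s = np.exp(eta)
        s /= s.sum(axis=1, keepdims=True)                 # softmax rows
        P = Q @ s                                         # N x J
        P = np.maximum(P, 1e-300)
        ll = float((Y * np.log(P)).sum())
        G = Q.T @ (Y / P)                                 # M x J
        g_eta = s * (G - (s * G).sum(axis=1, keepdims=True))
        gU = -(g_eta @ V) + 2.0 * lam * U
        gV = -(g_eta.T @ U) + 2.0 * lam * V
        gb = -g_eta.sum(axis=0)
        loss = -ll + lam * float((U ** 2).sum() + (V ** 2).sum())
        return loss * scale, np.concatenate([gU.ravel(), gV.ravel(), gb]) * scale

    x0 = 0.1 * rng.standard_normal(M * K + J * K + J)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": int(epochs) * 5, "ftol": 1e-12,
                            "gtol": 1e-9})
    U, V, b = unpack(res.x)

    train_ids = [s for s, t in zip(mic.sample_ids, train_mask) if t]
    test_ids = [s for s, t in zip(mic.sample_ids, train_mask) if not t]
    pooled = Y.sum(axis=0)
    pooled = pooled / pooled.sum()
    return CooccurrenceModel(
        U=pd.DataFrame(U, index=mic.feature_ids),
        V=pd.DataFrame(V, index=met.feature_ids),
        b=pd.Series(b, index=met.feature_ids),
        k=latent_dim,
        train_samples=train_ids,
        test_samples=test_ids,
        train_metabolite_proportions=pooled,
        hyperparameters={
            "latent_dim": latent_dim, "min_feature_count": min_feature_count,
            "epochs": epochs, "batch_size": batch_size,
            "learning_rate": learning_rate, "prior_sd": prior_sd,
            "training_fraction": training_fraction, "seed": seed,
            "converged": bool(res.success), "n_iterations": int(res.nit),
        },
    )


def pseudo_q2(
    model: CooccurrenceModel,
    heldout_microbes: FeatureTable,
    heldout_metabolites: FeatureTable,
) -> float:
    """Cross-validated predictive skill vs the pooled-proportion baseline.

    ``1 - NLL(model) / NLL(baseline)`` over held-out samples, where both
    negative log-likelihoods are per-observation multinomial and the baseline
    predicts the pooled training metabolite proportions for every sample.
    At most 1; 0 means no better than baseline; negative means worse.
    """
    if heldout_microbes.n_samples == 0:
        raise ValueError("empty hold-out set")
    if heldout_microbes.sample_ids != heldout_metabolites.sample_ids:
        raise ValueError("held-out tables must be sample-aligned")
    P = model.predict_proportions(heldout_microbes).values
    met = heldout_metabolites.select_features(model.metabolite_ids)
    Y = met.values
    baseline = np.asarray(model.train_metabolite_proportions, dtype=float)
    eps = 1e-300
    total = Y.sum()
    if total <= 0:
        raise ValueError("held-out metabolite table is all zero")
    nll_model = -float((Y * np.log(np.maximum(P, eps))).sum()) / total
    nll_base = -float((Y * np.log(np.maximum(baseline[None, :], eps))).sum()) / total
    return 1.0 - nll_model / nll_base


def cooccurrence_ordination(model: CooccurrenceModel):
    """Ordinate metabolites in microbial-taxon space.

    The co-occurrence matrix L is double-centred and decomposed by SVD; the
    singular values are split evenly between the two factor sets (each side
    scaled by sqrt of the singular values), so neither microbes nor
    metabolites absorb all the variance.  Distances between metabolite PC
    rows reflect similarity of co-occurrence profiles.

    Returns
    -------
    (metabolite_pcs, microbe_arrows, proportion_explained)
    """
    L = model.log_conditional().values
    centred = (L - L.mean(axis=1, keepdims=True)
               - L.mean(axis=0, keepdims=True) + L.mean())
    total = float((centred ** 2).sum())
    if total <= 1e-30:
        raise ValueError("degenerate (rank-0) co-occurrence matrix")
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(model.k, len(s))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for a in range(k):  # deterministic axis signs
        pivot = np.argmax(np.abs(vt[a]))
        if vt[a, pivot] < 0:
            vt[a] *= -1
            u[:, a] *= -1
    root = np.sqrt(s)
    metabolite_pcs = pd.DataFrame(vt.T * root[None, :], index=model.metabolite_ids,
                                  columns=[f"PC{a + 1}" for a in range(k)])
    microbe_arrows = pd.DataFrame(u * root[None, :], index=model.microbe_ids,
                                  columns=[f"PC{a + 1}" for a in range(k)])
    prop = (s ** 2) / total
    return metabolite_pcs, microbe_arrows, prop


def top_cooccurring(
    model: CooccurrenceModel,
    metabolite_set: list[str],
    k: int | None = 10,
    fraction: float | None = None,
) -> pd.Series:
    """Microbes ranked by mean co-occurrence strength with a metabolite set.

    Strength is the centred log conditional probability (per-microbe softmax
    constant removed) averaged over the requested metabolites.  Returns the
    top ``k`` microbes, or ``ceil(fraction * n_microbes)`` if ``fraction`` is
    given (exactly one of the two must be set).
    """
    if not metabolite_set:
        raise ValueError("metabolite_set must be nonempty")
    if fraction is not None and k is not None and k != 10:
        raise ValueError("set either k or fraction, not both")
    missing = [m for m in metabolite_set if m not in model.V.index]
    if missing:
        raise ValueError(f"unknown metabolites: {missing}")
    L = model.log_conditional(centred=True)
    strength = L[list(metabolite_set)].mean(axis=1)
    n = int(np.ceil(fraction * len(strength))) if fraction is not None else int(k)
    n = min(n, len(strength))
    order = strength.sort_values(ascending=False, kind="mergesort")
    return order.iloc[:n]
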