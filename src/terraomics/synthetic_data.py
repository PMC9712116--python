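"""Coupled microbe/metabolite study simulator with known ground truth.

The generator emulates the statistical skeleton of a cross-environment
multi-omics survey: samples are organised under a four-level EMPO-like
environment hierarchy; microbial counts are multinomial draws whose log
composition shifts by environment; metabolite intensities are generated
*conditionally on* the microbial composition through a latent co-occurrence
factor model; metabolite features are organised into molecular families
(connected network components), a subset of which are microbially derived and
carry seeded reference-database annotations; contaminant features show up in
extraction blanks; and both sequencing-depth and intensity noise (with zero
inflation) are applied.

The generative model
--------------------
Microbes (i = 1..M), environments (e), samples (n):

* baseline log-abundance  a_i ~ N(0, 1)
* environment effect      B_true[i, e] ~ N(0, differential_scale), with the
  reference (first) environment pinned at 0 for identifiability
* per-sample overdispersion eps_ni ~ N(0, overdispersion_sd); the default
  (1.5) makes different samples dominated by different microbes, as in real
  cross-environment surveys — this heterogeneity is what carries the
  co-occurrence signal into the metabolite table
* depth_n ~ Poisson(depth_mean);  counts_n ~ Mult(depth_n, softmax(a + B[:, e(n)] + eps_n))

Metabolites (j = 1..J), latent dimension k:

* U_true[i] ~ N(0, latent_scale)^k,  V_true[j] ~ N(0, 1)^k,
  bias b_true[j] ~ N(0, 1)
* conditional metabolite distribution per microbe:
  s_i = softmax_j(U_true[i] . V_true[j] + b_true[j])
* expected metabolite proportions  p_n = sum_i q_ni s_i  with q_n the
  *observed* microbial relative abundances of sample n (this is what couples
  the two tables)
* intensities = p_n * scale_n * lognormal(0, intensity_noise_sd), with
  scale_n ~ lognormal(ln 1e6, 0.5), then zeroed with probability
  zero_inflation_rate.

``simulate_decoupled`` replaces p_n by softmax(b_true) for every sample — a
negative control in which metabolites carry no microbial signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .tables_io import (
    AnnotationSet,
    FeatureTable,
    MolecularNetwork,
    SampleMetadata,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_study",
    "simulate_decoupled",
    "simulate_block_coupled",
]


@dataclass
class SimulationConfig:
    """Study-design knobs for the simulator.

    Defaults describe a small but fully structured survey: three leaf
    environments with 20 samples each, 50 microbes, 80 metabolites in 20
    molecular families, a rank-3 latent coupling, unit-scale environment
    effects, mean sequencing depth 5,000 and mild intensity noise with 10%
    zero inflation.
    """

    n_environments: int = 3
    samples_per_environment: int = 20
    n_microbes: int = 50
    n_metabolites: int = 80
    k_true: int = 3
    differential_scale: float = 1.0
    depth_mean: float = 5000.0
    intensity_noise_sd: float = 0.5
    zero_inflation_rate: float = 0.10
    n_families: int = 20
    seed_fraction: float = 0.30
    contaminant_fraction: float = 0.10
    n_studies: int = 2
    microbial_family_fraction: float = 0.5
    latent_scale: float = 2.5
    overdispersion_sd: float = 1.5
    intensity_scale_mu: float = np.log(1e6)
    intensity_scale_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_environments": self.n_environments,
            "samples_per_environment": self.samples_per_environment,
            "n_microbes": self.n_microbes,
            "n_metabolites": self.n_metabolites,
            "k_true": self.k_true,
            "n_families": self.n_families,
            "n_studies": self.n_studies,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        fracs = {
            "zero_inflation_rate": self.zero_inflation_rate,
            "seed_fraction": self.seed_fraction,
            "contaminant_fraction": self.contaminant_fraction,
            "microbial_family_fraction": self.microbial_family_fraction,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.differential_scale < 0 or self.intensity_noise_sd < 0:
            raise ValueError("scales must be nonnegative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.n_families > self.n_metabolites:
            raise ValueError("n_families cannot exceed n_metabolites")


@dataclass
class SyntheticTruth:
    """Ground-truth parameters recoverable by downstream estimators."""

    B_true: pd.DataFrame          # microbes x environments (reference col == 0)
    U_true: np.ndarray            # microbes x k
    V_true: np.ndarray            # metabolites x k
    b_true: np.ndarray            # metabolite biases
    origin_true: pd.Series        # metabolite -> bool (microbially related)
    family_of: pd.Series          # metabolite -> family id
    environment_of: pd.Series     # sample -> empo_4 label
    reference_environment: str = ""
    driver_block: Optional[dict] = None  # set for block-coupled simulations


def _empo_hierarchy(n_leaves: int) -> pd.DataFrame:
    """A consistent 4-level environment hierarchy with ``n_leaves`` leaves."""
    rows = []
    for i in range(n_leaves):
        empo_4 = f"env_{i:02d}"
        empo_3 = f"habitat_{i // 2:02d}"
        empo_2 = "saline" if (i // 4) % 2 else "non-saline"
        # level 2 must nest under one level-1 parent per value, so key level 1
        # off level 2 alone
        empo_1 = "free-living" if empo_2 == "non-saline" else "host-associated"
        rows.append((empo_1, empo_2, empo_3, empo_4))
    return pd.DataFrame(rows, columns=["empo_1", "empo_2", "empo_3", "empo_4"])


def _family_sizes(n_metabolites: int, n_families: int, rng: np.random.Generator) -> np.ndarray:
    """Family sizes from a truncated geometric so singleton families exist."""
    sizes = np.ones(n_families, dtype=int)
    remaining = n_metabolites - n_families
    if remaining > 0:
        extra = rng.geometric(p=0.35, size=n_families) - 1
        # distribute `remaining` proportionally to the geometric draws
        while remaining > 0:
            for f in np.argsort(-extra):
                take = min(int(extra[f]) if extra[f] > 0 else (1 if remaining > 0 else 0),
                           remaining)
                if take <= 0 and remaining > 0:
                    take = 1
                sizes[f] += take
                remaining -= take
                if remaining <= 0:
                    break
    assert sizes.sum() == n_metabolites
    return sizes


def _random_tree_edges(members: list[str], rng: np.random.Generator) -> list[tuple[str, str, float]]:
    """Uniform-ish random spanning tree: attach each node to a random earlier one."""
    edges = []
    for idx in range(1, len(members)):
        parent = int(rng.integers(0, idx))
        w = float(rng.uniform(0.7, 1.0))  # spectral cosine-like weight
        edges.append((members[parent], members[idx], w))
    return edges


def _simulate(config: SimulationConfig, coupled: bool,
              U_override: Optional[np.ndarray] = None,
              V_override: Optional[np.ndarray] = None):
    config.validate()
    rng = np.random.default_rng(config.seed)
    E, S = config.n_environments, config.samples_per_environment
    M, J, K = config.n_microbes, config.n_metabolites, config.k_true

    hierarchy = _empo_hierarchy(E)
    env_labels = list(hierarchy["empo_4"])
    reference_env = env_labels[0]

    microbe_ids = [f"OGU_{i:04d}" for i in range(M)]
    metab_ids = [f"mz_{j:04d}" for j in range(J)]

    # --- microbial truth and counts ---------------------------------------
    baseline = rng.normal(0.0, 1.0, size=M)
    B = rng.normal(0.0, config.differential_scale, size=(M, E))
    B[:, 0] = 0.0  # reference environment anchors the scale

    sample_ids, env_of, study_of, device_of = [], [], [], []
    devices_cycle = ["bulk", "swab", "filter"]
    for e, env in enumerate(env_labels):
        for s in range(S):
            sample_ids.append(f"S.{env}.{s:03d}")
            env_of.append(env)
            study_of.append(f"study_{(e + s) % config.n_studies:02d}")
            device_of.append(devices_cycle[e % 3])
    N = len(sample_ids)

    env_index = np.array([env_labels.index(e) for e in env_of])
    logits = baseline[None, :] + B[:, env_index].T \
        + rng.normal(0.0, config.overdispersion_sd, size=(N, M))
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    depths = np.maximum(rng.poisson(config.depth_mean, size=N), 1)
    counts = np.array([rng.multinomial(depths[n], probs[n]) for n in range(N)], dtype=float)

    # --- metabolite truth --------------------------------------------------
    U = (rng.normal(0.0, config.latent_scale, size=(M, K))
         if U_override is None else np.asarray(U_override, float))
    V = rng.normal(0.0, 1.0, size=(J, K)) if V_override is None else np.asarray(V_override, float)
    b = rng.normal(0.0, 1.0, size=J)

    eta = U @ V.T + b[None, :]                        # microbes x metabolites
    s_cond = np.exp(eta - eta.max(axis=1, keepdims=True))
    s_cond /= s_cond.sum(axis=1, keepdims=True)

    if coupled:
        q = counts / counts.sum(axis=1, keepdims=True)
        p = q @ s_cond                                # samples x metabolites
    else:
        sb = np.exp(b - b.max())
        p = np.tile(sb / sb.sum(), (N, 1))

    scale = rng.lognormal(config.intensity_scale_mu, config.intensity_scale_sd, size=N)
    noise = rng.lognormal(0.0, config.intensity_noise_sd, size=(N, J))
    intensities = p * scale[:, None] * noise
    dropout = rng.random((N, J)) < config.zero_inflation_rate
    intensities[dropout] = 0.0

    # --- molecular families, origin truth, annotations ---------------------
    sizes = _family_sizes(J, config.n_families, rng)
    family_of = {}
    edges: list[tuple[str, str, float]] = []
    start = 0
    family_members: list[list[str]] = []
    for f, size in enumerate(sizes):
        members = metab_ids[start:start + size]
        start += size
        family_members.append(members)
        for m in members:
            family_of[m] = f"family_{f:03d}"
        edges.extend(_random_tree_edges(members, rng))

    n_microbial = max(1, int(round(config.microbial_family_fraction * config.n_families)))
    microbial_families = set(rng.choice(config.n_families, size=n_microbial, replace=False))
    origin_true = pd.Series(
        {m: (f in microbial_families) for f, members in enumerate(family_members)
         for m in members}, name="origin_true").reindex(metab_ids)

    sources = pd.Series("none", index=metab_ids, dtype=object)
    hits: dict[str, set] = {m: set() for m in metab_ids}
    for f in microbial_families:
        members = family_members[f]
        n_seed = max(1, int(round(config.seed_fraction * len(members))))
        chosen = rng.choice(len(members), size=n_seed, replace=False)
        for c in chosen:
            m = members[int(c)]
            sources[m] = "library_match" if rng.random() < 0.7 else "dereplicator"
            hits[m].add("npatlas" if rng.random() < 0.6 else "mibig")

    # --- controls and contaminants -----------------------------------------
    n_contam = int(round(config.contaminant_fraction * J))
    # contaminants are extraction artifacts, so they never come from a
    # microbially derived molecular family
    non_microbial = [m for m in metab_ids if not origin_true[m]]
    contaminants = list(rng.choice(non_microbial,
                                   size=min(n_contam, len(non_microbial)),
                                   replace=False))

    blank_id = "CTRL.blank.000"
    blank_row = np.zeros(J)
    pos_ids, pos_rows, pos_devices = [], [], []
    if contaminants:
        cidx = [metab_ids.index(m) for m in contaminants]
        # blanks dominate the contaminant signal: sample max << 3x blank max
        col_max = intensities[:, cidx].max(axis=0)
        col_max[col_max == 0] = scale.mean()
        blank_row[cidx] = 5.0 * col_max
        # device positive controls each pick up a disjoint slice of contaminants
        for d, dev in enumerate(devices_cycle):
            row = np.zeros(J)
            slice_idx = cidx[d::3]
            if slice_idx:
                row[slice_idx] = col_max[[cidx.index(i) for i in slice_idx]]
            pos_ids.append(f"CTRL.pos.{dev}")
            pos_rows.append(row)
            pos_devices.append(dev)

    all_sample_ids = sample_ids + [blank_id] + pos_ids
    metab_values = np.vstack([intensities, blank_row[None, :]] +
                             ([np.vstack(pos_rows)] if pos_rows else []))
    # controls contribute no microbial reads; keep microbe table to real samples
    microbe_table = FeatureTable(counts, sample_ids, microbe_ids, kind="counts")
    metabolite_table = FeatureTable(metab_values, all_sample_ids, metab_ids,
                                    kind="intensities")

    # --- metadata -----------------------------------------------------------
    hier_map = hierarchy.set_index("empo_4")
    rows = []
    for sid, env, study, dev in zip(sample_ids, env_of, study_of, device_of):
        h = hier_map.loc[env]
        rows.append((sid, h["empo_1"], h["empo_2"], h["empo_3"], env, study, dev, "none"))
    rows.append((blank_id, "control", "control", "control", "control",
                 "study_00", "none", "negative_control"))
    for pid, dev in zip(pos_ids, pos_devices):
        rows.append((pid, "control", "control", "control", "control",
                     "study_00", dev, "positive_control"))
    md = pd.DataFrame(rows, columns=["sample_id", "empo_1", "empo_2", "empo_3",
                                     "empo_4", "study_id", "device",
                                     "control_role"]).set_index("sample_id")
    metadata = SampleMetadata(md)

    network = MolecularNetwork(nodes=list(metab_ids), edges=edges)
    annotations = AnnotationSet(pd.DataFrame(
        {"source": sources, "database_hits": [hits[m] for m in metab_ids]},
        index=pd.Index(metab_ids, name="feature_id")))

    truth = SyntheticTruth(
        B_true=pd.DataFrame(B, index=microbe_ids, columns=env_labels),
        U_true=U, V_true=V, b_true=b,
        origin_true=origin_true,
        family_of=pd.Series(family_of).reindex(metab_ids),
        environment_of=pd.Series(env_of, index=sample_ids),
        reference_environment=reference_env,
    )
    truth.contaminants = contaminants  # type: ignore[attr-defined]
    return microbe_table, metabolite_table, metadata, network, annotations, truth


def simulate_study(config: SimulationConfig):
    """Simulate a coupled microbe/metabolite study.

    Returns
    -------
    (microbe_table, metabolite_table, metadata, network, annotations, truth)
    """
    return _simulate(config, coupled=True)


def simulate_decoupled(config: SimulationConfig):
    """Same design but metabolites are generated ignoring the microbes.

    Serves as the negative control for co-occurrence and Mantel analyses:
    any apparent microbe-metabolite association is noise.
    """
    return _simulate(config, coupled=False)


def simulate_block_coupled(config: SimulationConfig, block_strength: float = 6.0):
    """Coupled simulation with an explicit two-block driver structure.

    The first half of the microbes drives the first half of the metabolites
    (and the second half the second half) with latent inner products elevated
    by ``block_strength``.  ``truth.driver_block`` maps block names to the
    microbe/metabolite id lists, for recovery checks of the co-occurrence
    ranking.
    """
    config.validate()
    M, J = config.n_microbes, config.n_metabolites
    K = max(2, config.k_true)
    rng = np.random.default_rng(config.seed + 101)
    U = rng.normal(0.0, 0.3, size=(M, K))
    V = rng.normal(0.0, 0.3, size=(J, K))
    half_m, half_j = M // 2, J // 2
    s = np.sqrt(block_strength)
    U[:half_m, 0] += s
    V[:half_j, 0] += s
    U[half_m:, 1] += s
    V[half_j:, 1] += s
    cfg = SimulationConfig(**{**config.__dict__, "k_true": K})
    out = _simulate(cfg, coupled=True, U_override=U, V_override=V)
    truth = out[-1]
    microbe_ids = out[0].feature_ids
    metab_ids = out[1].feature_ids
    truth.driver_block = {
        "block_1_microbes": microbe_ids[:half_m],
        "block_1_metabolites": metab_ids[:half_j],
        "block_2_microbes": microbe_ids[half_m:],
        "block_2_metabolites": metab_ids[half_j:],
    }
    return out
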