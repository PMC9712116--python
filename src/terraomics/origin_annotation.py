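"""Microbial-origin labelling of metabolite features.

Untargeted LC-MS/MS feature tables mix genuinely biological features with
extraction/gap-filling artifacts.  This module (1) removes features whose
signal is dominated by extraction blanks, (2) removes features traceable to
sampling-device positive controls, (3) seeds "microbially related" labels on
features with hits in microbial secondary-metabolite reference databases
(Natural Products Atlas, MIBiG), and (4) propagates those labels through
molecular families — the connected components of the spectral-similarity
molecular network — since structurally related metabolites share provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .tables_io import AnnotationSet, FeatureTable, MolecularNetwork, SampleMetadata

logger = logging.getLogger("terraomics")

__all__ = [
    "OriginLabels",
    "filter_gapfill_blanks",
    "filter_device_controls",
    "seed_microbial",
    "propagate",
    "subset_microbial",
]


@dataclass
class OriginLabels:
    """Per-feature origin status: ``seed`` (direct database hit),
    ``propagated`` (same molecular family as a seed), or ``unlabeled``."""

    status: pd.Series  # feature_id -> {"seed", "propagated", "unlabeled"}

    def __post_init__(self) -> None:
        bad = set(self.status.unique()) - {"seed", "propagated", "unlabeled"}
        if bad:
            raise ValueError(f"unknown origin status values: {sorted(bad)}")

    @property
    def labeled_ids(self) -> list[str]:
        return list(self.status.index[self.status.isin(["seed", "propagated"])])

    @property
    def n_labeled(self) -> int:
        return int(self.status.isin(["seed", "propagated"]).sum())


def filter_gapfill_blanks(
    table: FeatureTable,
    metadata: SampleMetadata,
    ratio_threshold: float = 3.0,
) -> FeatureTable:
    """Drop features whose real-sample signal is blank-dominated.

    A feature is kept only when its maximum intensity across true samples
    strictly exceeds ``ratio_threshold`` times its maximum intensity across
    negative-control (blank) samples (so at the boundary the feature is
    removed).  Features never seen in a blank are kept unconditionally.
    """
    if table.kind != "intensities":
        raise ValueError("blank filtering applies to intensity tables")
    blanks = [s for s in metadata.negative_controls() if s in table.sample_ids]
    if not blanks:
        raise ValueError(
            "no negative-control samples in metadata/table; if the study has "
            "no blanks, skip this filter explicitly rather than calling it"
        )
    real = [s for s in metadata.real_samples() if s in table.sample_ids]
    df = table.to_dataframe()
    blank_max = df.loc[blanks].max(axis=0)
    real_max = df.loc[real].max(axis=0) if real else pd.Series(0.0, index=df.columns)
    keep = (blank_max == 0) | (real_max > ratio_threshold * blank_max)
    kept_ids = list(df.columns[keep])
    n_removed = table.n_features - len(kept_ids)
    logger.info("blank filter removed %d/%d features", n_removed, table.n_features)
    return table.select_features(kept_ids)


def filter_device_controls(table: FeatureTable, metadata: SampleMetadata) -> FeatureTable:
    """Zero out features detected in a device's positive control, but only in
    samples collected with that device; drop features left all-zero."""
    pos = [s for s in metadata.positive_controls() if s in table.sample_ids]
    if not pos:
        logger.warning("no positive-control samples; device filter is a no-op")
        return table.copy()
    df = table.to_dataframe().copy()
    md = metadata.frame
    for ctrl in pos:
        device = md.loc[ctrl, "device"]
        if device == "none":
            continue
        contaminated = df.columns[df.loc[ctrl] > 0]
        same_device_samples = [
            s for s in table.sample_ids
            if s in md.index and md.loc[s, "control_role"] == "none"
            and md.loc[s, "device"] == device
        ]
        df.loc[same_device_samples, contaminated] = 0.0
    real = [s for s in table.sample_ids
            if s in md.index and md.loc[s, "control_role"] == "none"]
    keep = df.loc[real].sum(axis=0) > 0 if real else df.sum(axis=0) > 0
    kept_ids = list(df.columns[keep])
    out = FeatureTable(df.values, table.sample_ids, list(df.columns), table.kind)
    return out.select_features(kept_ids)


def seed_microbial(annotations: AnnotationSet) -> set[str]:
    """Features with a hit in a microbial reference database (npatlas/mibig).

    Annotation sources without database membership (e.g. a bare spectral
    library match) do not seed.
    """
    hits = annotations.frame["database_hits"]
    return {fid for fid, h in hits.items() if set(h) & {"npatlas", "mibig"}}


def propagate(network: MolecularNetwork, seeds: set[str]) -> OriginLabels:
    """Spread microbial-origin labels across molecular families.

    Every node sharing a connected component with at least one seed becomes
    ``propagated`` (the seeds themselves stay ``seed``); all other nodes are
    ``unlabeled``.  Edge weights are ignored: family membership alone decides.
    Idempotent — relabelling an already-labelled network changes nothing.
    """
    g = network.to_networkx()
    unknown = sorted(s for s in seeds if s not in g.nodes)
    if unknown:
        raise ValueError(f"seed ids absent from the network node universe: {unknown}")
    status = pd.Series("unlabeled", index=pd.Index(network.nodes, dtype=object))
    for comp in nx.connected_components(g):
        comp_seeds = comp & seeds
        if comp_seeds:
            for node in comp:
                status[node] = "seed" if node in comp_seeds else "propagated"
    return OriginLabels(status=status)


def subset_microbial(table: FeatureTable, labels: OriginLabels) -> FeatureTable:
    """Restrict a metabolite table to microbially related features."""
    missing = [f for f in table.feature_ids if f not in labels.status.index]
    if missing:
        raise ValueError(f"labels do not cover table features: {missing[:5]}...")
    keep = [f for f in table.feature_ids
            if labels.status[f] in ("seed", "propagated")]
    if not keep:
        logger.warning("no microbially related features; returning empty table")
        return FeatureTable(np.empty((table.n_samples, 0)), list(table.sample_ids),
                            [], table.kind)
    return table.select_features(keep)
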