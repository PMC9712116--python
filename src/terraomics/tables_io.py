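"""Core containers and on-disk formats.

Every artifact exchanged between pipeline stages lives here: sample-by-feature
abundance tables, per-sample environment metadata following a four-level
EMPO-style hierarchy, square distance matrices, molecular networks (undirected
edge lists), annotation records and rooted phylogenies.

Conventions
-----------
* Feature tables are stored on disk with features as rows and samples as
  columns (the common feature-table export orientation); in memory the
  orientation is samples x features.
* Metadata is a QIIME-style TSV: tab-delimited, UTF-8, first column header
  ``sample_id``, lines starting with ``#`` ignored.
* Distance matrices are square TSVs with sample ids on both axes.
* Phylogenies are Newick; missing branch lengths are treated as zero with a
  warning so that phylogenetic diversity stays defined.

All stochastic operations take an explicit integer seed; no function touches
global random state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger("terraomics")

EMPO_COLUMNS = ("empo_1", "empo_2", "empo_3", "empo_4")
DEVICES = ("bulk", "swab", "filter", "none")
CONTROL_ROLES = ("none", "negative_control", "positive_control")


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Nonnegative samples x features abundance matrix.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Counts or intensities; must be nonnegative.
    sample_ids, feature_ids : sequences of unique strings
    kind : {"counts", "intensities"}
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.kind not in ("counts", "intensities"):
            raise ValueError(f"kind must be 'counts' or 'intensities', got {self.kind!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at "
                f"(feature={self.feature_ids[j]!r}, sample={self.sample_ids[i]!r})"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_dataframe(self) -> pd.DataFrame:
        """Samples x features DataFrame view."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_samples(self, ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in ids]
        return FeatureTable(self.values[idx], list(ids), list(self.feature_ids), self.kind)

    def select_features(self, ids: Sequence[str]) -> "FeatureTable":
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in ids]
        return FeatureTable(self.values[:, idx], list(self.sample_ids), list(ids), self.kind)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), list(self.sample_ids),
                            list(self.feature_ids), self.kind)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for s in ids:
        if s in seen:
            dups.append(s)
        seen[s] = 1
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(set(dups))}")


def read_feature_table(path: str | Path, kind: str = "counts") -> FeatureTable:
    """Read a feature table from TSV (features as rows) or BIOM-JSON.

    For TSV, the first cell is a header token (e.g. ``feature_id``) and the
    remaining header cells are sample ids.  Files whose content starts with
    ``{`` are parsed as sparse BIOM v1 (JSON).  Zero rows and columns are
    preserved.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.read(1)
    if head == "{":
        return _read_biom_json(path, kind)
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df.values.T, list(df.columns), list(df.index), kind)


def _read_biom_json(path: Path, kind: str) -> FeatureTable:
    """Sparse BIOM v1 (JSON): observations are features (rows), columns are
    samples; ``data`` holds [row, col, value] triples when sparse."""
    import json

    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    feature_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    values = np.zeros((len(sample_ids), len(feature_ids)))
    if doc.get("matrix_type", "sparse") == "sparse":
        for i, j, v in doc["data"]:
            values[int(j), int(i)] = float(v)
    else:
        dense = np.asarray(doc["data"], dtype=float)
        values = dense.T
    return FeatureTable(values, sample_ids, feature_ids, kind)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write features-as-rows TSV (inverse of :func:`read_feature_table`)."""
    df = pd.DataFrame(table.values.T, index=table.feature_ids, columns=table.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample study design: EMPO levels 1-4, study id, device, control role.

    The EMPO hierarchy must be consistent: each level-4 value maps to exactly
    one level-3 parent, each level-3 to one level-2, each level-2 to one
    level-1.  Control samples carry ``control_role`` of ``negative_control``
    or ``positive_control``; real samples use ``none``.
    """

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        required = list(EMPO_COLUMNS) + ["study_id", "device", "control_role"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad_dev = set(self.frame["device"]) - set(DEVICES)
        if bad_dev:
            raise ValueError(f"unknown device values: {sorted(bad_dev)}")
        bad_role = set(self.frame["control_role"]) - set(CONTROL_ROLES)
        if bad_role:
            raise ValueError(f"unknown control_role values: {sorted(bad_role)}")
        self._validate_hierarchy()

    def _validate_hierarchy(self) -> None:
        for child, parent in zip(EMPO_COLUMNS[:0:-1], EMPO_COLUMNS[-2::-1]):
            mapping = self.frame.groupby(child)[parent].nunique()
            bad = mapping[mapping > 1]
            if len(bad):
                raise ValueError(
                    f"EMPO hierarchy inconsistent: {child} value(s) "
                    f"{bad.index.tolist()} appear under multiple {parent} parents"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index.astype(str))

    def environments(self, level: int = 4) -> pd.Series:
        """EMPO labels at the given level for non-control samples."""
        return self.frame.loc[self.frame["control_role"] == "none", f"empo_{level}"]

    def real_samples(self) -> list[str]:
        return list(self.frame.index[self.frame["control_role"] == "none"])

    def negative_controls(self) -> list[str]:
        return list(self.frame.index[self.frame["control_role"] == "negative_control"])

    def positive_controls(self) -> list[str]:
        return list(self.frame.index[self.frame["control_role"] == "positive_control"])

    def select(self, ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(ids)].copy())


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"first metadata column must be 'sample_id', got {df.columns[0]!r}")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(md: SampleMetadata, path: str | Path) -> None:
    out = md.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# DistanceMatrix (thin wrapper over scikit-bio)
# ---------------------------------------------------------------------------

def make_distance_matrix(data: np.ndarray, ids: Sequence[str]) -> skbio.DistanceMatrix:
    """Validated square symmetric zero-diagonal distance matrix."""
    return skbio.DistanceMatrix(np.asarray(data, dtype=float), ids=list(ids))


def read_distance_matrix(path: str | Path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column ids differ")
    vals = df.values
    # symmetrize away representation round-off from text serialization
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    return skbio.DistanceMatrix(vals, ids=list(df.index))


def write_distance_matrix(dm: skbio.DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Molecular network + annotations
# ---------------------------------------------------------------------------

@dataclass
class MolecularNetwork:
    """Undirected metabolite-feature graph; molecular families are its
    connected components.  Extra table features may be absent from the edge
    list; they are treated as isolated nodes."""

    nodes: list[str]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        cleaned = []
        for e in self.edges:
            a, b = str(e[0]), str(e[1])
            w = float(e[2]) if len(e) > 2 else 1.0
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            node_set.update((a, b))
            cleaned.append((a, b, w))
        self.edges = cleaned
        self.nodes = sorted(node_set)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


def read_network(path: str | Path) -> MolecularNetwork:
    """Edge-list TSV with columns (source, target[, weight])."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    edges = []
    for row in df.itertuples(index=False):
        w = float(row[2]) if len(row) > 2 else 1.0
        edges.append((str(row[0]), str(row[1]), w))
    return MolecularNetwork(nodes=[], edges=edges)


def write_network(net: MolecularNetwork, path: str | Path) -> None:
    df = pd.DataFrame(net.edges, columns=["source", "target", "weight"])
    df.to_csv(path, sep="\t", index=False)
    # isolated nodes are reconstructed from the companion table on read


@dataclass
class AnnotationSet:
    """Per-feature annotation records.

    ``source`` is how the feature was annotated (spectral library match,
    dereplicator hit, or none); ``database_hits`` records membership in
    microbial secondary-metabolite reference databases (npatlas, mibig).
    A database hit implies an annotation source.
    """

    frame: pd.DataFrame  # index feature_id; columns: source, database_hits (set)

    def __post_init__(self) -> None:
        for col in ("source", "database_hits"):
            if col not in self.frame.columns:
                raise ValueError(f"annotation frame missing column {col!r}")
        bad = set(self.frame["source"]) - {"library_match", "dereplicator", "none"}
        if bad:
            raise ValueError(f"unknown annotation sources: {sorted(bad)}")
        for fid, row in self.frame.iterrows():
            hits = set(row["database_hits"])
            unknown = hits - {"npatlas", "mibig"}
            if unknown:
                raise ValueError(f"unknown database hits {sorted(unknown)} for {fid!r}")
            if hits and row["source"] == "none":
                raise ValueError(f"feature {fid!r} has database hits but source 'none'")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index.astype(str))


def read_annotations(path: str | Path) -> AnnotationSet:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    df.index = df.index.astype(str)
    hits = [set(h.split(",")) - {""} for h in df["database_hits"]]
    return AnnotationSet(pd.DataFrame({"source": df["source"], "database_hits": hits},
                                      index=df.index))


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    out = pd.DataFrame({
        "source": ann.frame["source"],
        "database_hits": [",".join(sorted(h)) for h in ann.frame["database_hits"]],
    }, index=ann.frame.index)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0 (warned)."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(f"{n_missing} branches had no length; set to 0", stacklevel=2)
    tips = [t.name for t in tree.tips()]
    _check_unique(tips, "tip")
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Alignment and rarefaction
# ---------------------------------------------------------------------------

def align(
    table_a: FeatureTable,
    table_b: FeatureTable,
    metadata: SampleMetadata,
) -> tuple[FeatureTable, FeatureTable, SampleMetadata]:
    """Restrict two tables and metadata to their shared samples, in one order.

    The shared order is the order of appearance in ``table_a``.
    """
    in_b = set(table_b.sample_ids)
    in_md = set(metadata.sample_ids)
    shared = [s for s in table_a.sample_ids if s in in_b and s in in_md]
    if not shared:
        raise ValueError("no shared samples between tables and metadata")
    return (table_a.select_samples(shared), table_b.select_samples(shared),
            metadata.select(shared))


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped.  Only defined for
    count tables.
    """
    if table.kind != "counts":
        raise ValueError("rarefaction is undefined for intensity tables")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.rint(table.values).astype(np.int64)
    keep, rows = [], []
    for i, sid in enumerate(table.sample_ids):
        total = counts[i].sum()
        if total < depth:
            continue
        # multivariate hypergeometric = subsampling reads without replacement
        rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        keep.append(sid)
    if not keep:
        raise ValueError(f"no sample reaches depth {depth}")
    return FeatureTable(np.array(rows, dtype=float), keep, list(table.feature_ids), "counts")
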