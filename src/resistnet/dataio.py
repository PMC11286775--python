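"""Readers and writers for the tabular formats the pipeline touches.

All formats are plain text: TSV matrices with a header row and feature ids
in the first column, sample-metadata TSV (``sample_id``, ``condition``),
STRING-style edge lists, four-column regulon tables and Broad-dialect GMT
gene-set files.  Feature identifiers are opaque strings; no alias or
ortholog mapping is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates its format contract."""


class MetadataError(ValueError):
    """Sample metadata does not cover the expression matrix."""


@dataclass
class ExpressionMatrix:
    """A features x samples matrix of counts or intensities.

    ``data`` is a pandas DataFrame (rows = features, columns = samples);
    missing intensities are carried as NaN and excluded pairwise downstream.
    ``conditions`` maps every sample to its condition label.
    """

    data: pd.DataFrame
    conditions: pd.Series
    kind: str = "count"

    def __post_init__(self) -> None:
        if self.kind not in ("count", "intensity"):
            raise ValueError(f"kind must be 'count' or 'intensity', got {self.kind!r}")
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate feature id(s): {sorted(set(dup))}")
        dup = self.data.columns[self.data.columns.duplicated()]
        if len(dup):
            raise FormatError(f"duplicate sample id(s): {sorted(set(dup))}")
        missing = [s for s in self.data.columns if s not in self.conditions.index]
        if missing:
            raise MetadataError(f"samples without condition label: {missing}")
        self.conditions = self.conditions.reindex(self.data.columns)
        vals = self.data.to_numpy()
        if self.kind == "count":
            if np.isnan(vals).any():
                raise FormatError("count matrix contains missing values")
            if (vals < 0).any():
                raise FormatError("count matrix contains negative values")
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("count matrix contains non-integer values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[samples], self.conditions.loc[samples], self.kind)


@dataclass
class Regulon:
    """One regulator's targets with mode of regulation and confidence weight."""

    targets: list[str]
    mor: np.ndarray  # in [-1, 1]
    likelihood: np.ndarray  # >= 0

    def __post_init__(self) -> None:
        self.mor = np.asarray(self.mor, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if len(self.targets) != len(self.mor) or len(self.targets) != len(self.likelihood):
            raise FormatError("regulon fields have inconsistent lengths")
        if len(set(self.targets)) != len(self.targets):
            raise FormatError("duplicate target within one regulon")
        if np.any(np.abs(self.mor) > 1):
            raise FormatError("mode of regulation outside [-1, 1]")
        if np.any(self.likelihood < 0) or not np.any(self.likelihood > 0):
            raise FormatError("likelihood weights must be >= 0 with at least one positive")

    @property
    def target_set(self) -> frozenset:
        return frozenset(self.targets)


class RegulonSet(dict):
    """Mapping regulator id -> :class:`Regulon`."""


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of feature ids with optional descriptions."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = set(members)

    def __getitem__(self, name):
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_matrix(path, kind: str, metadata_path) -> ExpressionMatrix:
    """Read a features x samples TSV plus a sample->condition metadata TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise FormatError(
                f"non-numeric value(s) in column {col!r}: {bad.head().to_dict()}"
            )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample_id", "condition"} <= set(meta.columns):
        raise MetadataError("metadata must have columns sample_id and condition")
    conditions = pd.Series(meta["condition"].values, index=meta["sample_id"].values)
    return ExpressionMatrix(df.astype(float), conditions, kind)


def write_matrix(mat: ExpressionMatrix, path, metadata_path=None) -> None:
    mat.data.to_csv(path, sep="\t", index_label="feature_id")
    if metadata_path is not None:
        pd.DataFrame(
            {"sample_id": mat.sample_ids, "condition": mat.conditions.values}
        ).to_csv(metadata_path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (name, description, members...)."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"duplicate gene-set name {name!r}")
            members = [m for m in fields[2:] if m]
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")


def read_ppi_edges(path, score_threshold: float = 0.4) -> nx.Graph:
    """Read an edge-list TSV into a simple undirected scored graph.

    Scores on the STRING 0-1000 scale are auto-detected (any score > 1)
    and divided by 1000.  Self-loops are dropped, duplicate edges keep the
    maximum score, and edges below ``score_threshold`` are discarded.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("empty PPI edge file %s", path)
        return nx.Graph()
    if df.empty:
        logger.warning("empty PPI edge file %s", path)
        return nx.Graph()
    if df.shape[1] < 3:
        raise FormatError("PPI edge list needs 3 columns: node, node, score")
    # tolerate a header row naming the columns
    first = pd.to_numeric(df.iloc[0, 2], errors="coerce")
    if math.isnan(first):
        df = df.iloc[1:]
        if df.empty:
            logger.warning("PPI edge file %s has a header but no edges", path)
            return nx.Graph()
    scores = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    if scores.isna().any():
        raise FormatError("non-numeric combined score in PPI edge list")
    scores = scores.to_numpy(dtype=float)
    if np.any(scores > 1):
        scores = scores / 1000.0
    graph = nx.Graph()
    for (u, v), score in zip(df.iloc[:, :2].itertuples(index=False), scores):
        if u == v or score < score_threshold:
            continue
        if graph.has_edge(u, v):
            graph[u][v]["score"] = max(graph[u][v]["score"], score)
        else:
            graph.add_edge(u, v, score=score)
    if graph.number_of_edges() == 0:
        logger.warning("no PPI edges retained at threshold %.2f", score_threshold)
    return graph


def write_ppi_edges(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('score', 1.0):.6g}\n")


def read_regulons(path) -> RegulonSet:
    """Read a (regulator, target, mor, likelihood) TSV into a RegulonSet."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    expected = ["regulator", "target", "mor", "likelihood"]
    if list(df.columns[:4]) != expected:
        raise FormatError(f"regulon table must have columns {expected}")
    if df.duplicated(subset=["regulator", "target"]).any():
        dup = df[df.duplicated(subset=["regulator", "target"])].iloc[0]
        raise FormatError(f"duplicate (regulator, target) pair: {dup.regulator}/{dup.target}")
    if (df["mor"].abs() > 1).any():
        bad = df.loc[df["mor"].abs() > 1].iloc[0]
        raise FormatError(f"mor outside [-1, 1] for {bad.regulator}/{bad.target}: {bad.mor}")
    regulons = RegulonSet()
    for reg, grp in df.groupby("regulator", sort=False):
        regulons[reg] = Regulon(
            list(grp["target"]),
            grp["mor"].to_numpy(dtype=float),
            grp["likelihood"].to_numpy(dtype=float),
        )
    return regulons


def write_regulons(regulons: RegulonSet, path) -> None:
    rows = []
    for reg, regulon in regulons.items():
        for t, m, w in zip(regulon.targets, regulon.mor, regulon.likelihood):
            rows.append((reg, t, m, w))
    pd.DataFrame(rows, columns=["regulator", "target", "mor", "likelihood"]).to_csv(
        path, sep="\t", index=False
    )
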