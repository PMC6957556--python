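"""Weighted graph-topology measures on functional-connectivity matrices.

The connectome is analyzed fully weighted — no thresholding or
binarization — on the complete coherence matrix. Conventions:

* shortest-path edge length is the reciprocal of the connection weight
  (``1/w``; a ``-log(w)`` alternative is exposed), so strong connections are
  short;
* global efficiency is the mean over ordered node pairs of the inverse
  shortest weighted path length; disconnected pairs contribute zero;
* weighted clustering uses the Onnela geometric-mean-of-triangles form on
  weights normalized by the maximum off-diagonal weight, which is bounded in
  [0, 1] and reduces to the classic proportion-of-triangles definition on
  binary graphs.

Subnetwork (per-RSN) metrics are computed on the induced subgraph of the
member nodes, so within-network paths may not route through out-of-network
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

RSN_NAMES = ("DMN", "FPN", "DAN", "VAN")
OTHER_LABEL = "other"

__all__ = [
    "RSN_NAMES",
    "OTHER_LABEL",
    "CoherenceMatrix",
    "NetworkPartition",
    "TopologyMetrics",
    "global_efficiency",
    "clustering_coefficient",
    "subnetwork_metrics",
    "within_network_fc",
    "between_network_fc",
    "compute_topology_metrics",
    "metrics_table",
]


@dataclass
class CoherenceMatrix:
    """Symmetric node-by-node band-averaged coherence FC matrix in [0, 1]."""

    values: np.ndarray
    node_ids: list[str]
    band_hz: tuple[float, float] = (0.06, 0.12)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} node ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("coherence matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("coherence values must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def submatrix(self, ids: list[str]) -> "CoherenceMatrix":
        idx = [self.node_ids.index(i) for i in ids]
        return CoherenceMatrix(self.values[np.ix_(idx, idx)], list(ids), self.band_hz)


@dataclass
class NetworkPartition:
    """Node -> resting-state-network label (DMN/FPN/DAN/VAN/other)."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        allowed = set(RSN_NAMES) | {OTHER_LABEL}
        bad = {v for v in self.labels.values() if v not in allowed}
        if bad:
            raise ValueError(f"unknown network labels: {sorted(bad)}")

    def members(self, label: str) -> list[str]:
        return [n for n, v in self.labels.items() if v == label]

    def restrict(self, node_ids: list[str]) -> "NetworkPartition":
        missing = [n for n in node_ids if n not in self.labels]
        if missing:
            raise ValueError(f"nodes without a network label: {missing[:5]}")
        return NetworkPartition({n: self.labels[n] for n in node_ids})

    def validate_rsns_nonempty(self) -> None:
        for name in RSN_NAMES:
            if not self.members(name):
                raise ValueError(f"network {name} has no member nodes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": list(self.labels), "network": list(self.labels.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NetworkPartition":
        return cls(dict(zip(df["node_id"].astype(str), df["network"])))


@dataclass
class TopologyMetrics:
    """Per-subject topology summary consumed by the regression stage."""

    global_efficiency: float
    global_clustering: float
    rsn_efficiency: dict[str, float]
    rsn_clustering: dict[str, float]
    within_fc: dict[str, float]
    between_fc: dict[tuple[str, str], float]
    extras: dict[str, float] = field(default_factory=dict)


def _weights(matrix: CoherenceMatrix | np.ndarray) -> np.ndarray:
    w = matrix.values if isinstance(matrix, CoherenceMatrix) else np.asarray(matrix, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    if (w < 0).any():
        raise ValueError("connection weights must be nonnegative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)  # diagonal excluded from every measure
    return w


def global_efficiency(
    matrix: CoherenceMatrix | np.ndarray, edge_length: str = "inverse"
) -> float:
    """Mean inverse shortest weighted path length over ordered node pairs."""
    w = _weights(matrix)
    n = w.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    with np.errstate(divide="ignore"):
        if edge_length == "inverse":
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        elif edge_length == "neglog":
            lengths = np.where(w > 0, -np.log(np.clip(w, 1e-300, 1.0)), np.inf)
        else:
            raise ValueError(f"unknown edge_length convention: {edge_length!r}")
    lengths[~np.isfinite(lengths)] = 0.0  # csgraph treats 0 as "no edge"
    d = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0  # disconnected pairs contribute zero
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(
    matrix: CoherenceMatrix | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node and its network mean (Gcc).

    Weights are normalized by the maximum off-diagonal weight; per node,
    the geometric mean of triangle weights is averaged over neighbor pairs.
    Nodes with fewer than 2 neighbors get clustering 0.
    """
    w = _weights(matrix)
    n = w.shape[0]
    if n < 3:
        raise ValueError("clustering is undefined for fewer than 3 nodes")
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n), 0.0
    what = np.cbrt(w / wmax)
    triangles = np.diagonal(what @ what @ what)  # 2 x sum of triangle geometric means
    degree = (w > 0).sum(axis=1)
    denom = degree * (degree - 1)
    per_node = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return per_node, float(per_node.mean())


def subnetwork_metrics(
    matrix: CoherenceMatrix,
    partition: NetworkPartition,
    label: str,
    edge_length: str = "inverse",
) -> tuple[float, float]:
    """(efficiency, mean clustering) of the induced within-network subgraph."""
    if label not in RSN_NAMES:
        raise ValueError(f"unknown subnetwork label {label!r}, expected one of {RSN_NAMES}")
    members = [n for n in matrix.node_ids if partition.labels.get(n) == label]
    if len(members) < 3:
        raise ValueError(f"subnetwork {label} has {len(members)} nodes; need >= 3")
    sub = matrix.submatrix(members)
    eff = global_efficiency(sub, edge_length=edge_length)
    _, gcc = clustering_coefficient(sub)
    return eff, gcc


def _block_indices(matrix: CoherenceMatrix, partition: NetworkPartition, label: str):
    idx = [i for i, n in enumerate(matrix.node_ids) if partition.labels.get(n) == label]
    if not idx:
        raise ValueError(f"network {label} has no nodes in this matrix")
    return np.asarray(idx)


def within_network_fc(
    matrix: CoherenceMatrix, partition: NetworkPartition, labels=RSN_NAMES
) -> dict[str, float]:
    """Mean FC over unordered distinct node pairs inside each network."""
    out = {}
    for label in labels:
        idx = _block_indices(matrix, partition, label)
        if len(idx) < 2:
            raise ValueError(f"network {label} needs >= 2 nodes for within-network FC")
        block = matrix.values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        out[label] = float(block[iu].mean())
    return out


def between_network_fc(
    matrix: CoherenceMatrix, partition: NetworkPartition, labels=RSN_NAMES
) -> dict[tuple[str, str], float]:
    """Mean FC over all cross-network node pairs, one value per network pair."""
    out = {}
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            a, b = labels[a_i], labels[b_i]
            ia = _block_indices(matrix, partition, a)
            ib = _block_indices(matrix, partition, b)
            out[(a, b)] = float(matrix.values[np.ix_(ia, ib)].mean())
    return out


def compute_topology_metrics(
    matrix: CoherenceMatrix,
    partition: NetworkPartition,
    edge_length: str = "inverse",
) -> TopologyMetrics:
    """All measures used downstream: GE, Gcc, per-RSN, within/between FC."""
    part = partition.restrict(matrix.node_ids)
    part.validate_rsns_nonempty()
    _, gcc = clustering_coefficient(matrix)
    rsn_eff, rsn_cc = {}, {}
    for name in RSN_NAMES:
        rsn_eff[name], rsn_cc[name] = subnetwork_metrics(
            matrix, part, name, edge_length=edge_length
        )
    return TopologyMetrics(
        global_efficiency=global_efficiency(matrix, edge_length=edge_length),
        global_clustering=gcc,
        rsn_efficiency=rsn_eff,
        rsn_clustering=rsn_cc,
        within_fc=within_network_fc(matrix, part),
        between_fc=between_network_fc(matrix, part),
    )


def metrics_table(per_subject: dict[str, TopologyMetrics]) -> pd.DataFrame:
    """One row per subject: GE, Gcc, 4x2 subnetwork metrics, 4 within-FC, 6 between-FC."""
    rows = []
    for sid, m in per_subject.items():
        row: dict[str, float | str] = {"subject_id": sid}
        row["GE"] = m.global_efficiency
        row["Gcc"] = m.global_clustering
        for name in RSN_NAMES:
            row[f"eff_{name}"] = m.rsn_efficiency[name]
            row[f"cc_{name}"] = m.rsn_clustering[name]
        for name in RSN_NAMES:
            row[f"fc_within_{name}"] = m.within_fc[name]
        for (a, b), v in m.between_fc.items():
            row[f"fc_{a}_{b}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
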