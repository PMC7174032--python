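"""Graph-theoretic measures on weighted connectomes.

Conventions (standard in structural connectomics):

* degree centrality is the binary count of surviving (nonzero) edges — after
  control-referenced thresholding it indexes dysconnectivity;
* edges are mapped to lengths by l_ij = 1 / w_ij, so stronger connections are
  shorter, and shortest paths are computed on those lengths;
* global efficiency is the mean inverse shortest-path length over ordered
  node pairs, with disconnected pairs contributing zero;
* local efficiency of node i is the global efficiency of the subgraph induced
  by its neighbours (zero with fewer than two neighbours);
* the clustering coefficient uses the Onnela geometric-mean form on weights
  normalized by the network maximum, so it lies in [0, 1];
* hubs are the top 20% (floor) of subnetwork nodes by control-average degree.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import Connectome, SubnetworkDefinition

GLOBAL_METRICS = ("global_efficiency", "avg_local_efficiency", "avg_degree")
NODAL_METRICS = ("degree", "local_efficiency", "clustering")


def _weights(c: Connectome | np.ndarray) -> np.ndarray:
    return c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)


def degree_centrality(c: Connectome | np.ndarray) -> np.ndarray:
    """Number of nonzero incident edges per node."""
    w = _weights(c)
    return (w > 0).sum(axis=1).astype(float)


def strength(c: Connectome | np.ndarray) -> np.ndarray:
    """Weighted degree (sum of incident edge weights) — documented alternative."""
    return _weights(c).sum(axis=1)


def shortest_path_lengths(c: Connectome | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on l = 1/w; inf where disconnected."""
    w = _weights(c)
    if w.shape[0] == 0:
        return np.zeros((0, 0))
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    # csgraph dense convention: 0 entries are absent edges
    return _csgraph_shortest_path(lengths, method="D", directed=False)


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(c: Connectome | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered pairs (1/inf = 0)."""
    w = _weights(c)
    if w.shape[0] < 2:
        raise ValueError("global efficiency requires at least two nodes")
    return _efficiency_from_distances(shortest_path_lengths(w))


def local_efficiency(c: Connectome | np.ndarray) -> np.ndarray:
    """Per-node global efficiency of the neighbour-induced subgraph."""
    w = _weights(c)
    n = w.shape[0]
    out = np.zeros(n)
    adj = w > 0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        out[i] = _efficiency_from_distances(shortest_path_lengths(sub))
    return out


def clustering_coefficient(c: Connectome | np.ndarray) -> np.ndarray:
    """Onnela weighted clustering on max-normalized weights, in [0, 1]."""
    w = _weights(c)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    cbrt = np.cbrt(w / wmax)
    triangles = np.einsum("ij,jk,ki->i", cbrt, cbrt, cbrt)
    k = degree_centrality(w)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, triangles / denom, 0.0)
    return out


def identify_hubs(
    control_connectomes: Iterable[Connectome | np.ndarray],
    d: SubnetworkDefinition,
    node_labels: Sequence[str] | None = None,
    fraction: float = 0.2,
) -> list[str]:
    """Top-``fraction`` (floor) subnetwork nodes by control-average degree.

    Degrees are computed on the full connectomes, then averaged over controls
    and restricted to the subnetwork members; ties are broken by member list
    order (earlier label wins).
    """
    controls = list(control_connectomes)
    if len(controls) == 0:
        raise ValueError("at least one control connectome is required")
    stack = [_weights(c) for c in controls]
    if node_labels is None:
        first = next((c for c in controls if isinstance(c, Connectome)), None)
        if first is None:
            raise ValueError("node_labels required when passing raw arrays")
        node_labels = first.node_labels
    avg_degree = np.mean([(w > 0).sum(axis=1) for w in stack], axis=0)
    idx = d.indices(node_labels)
    n_hubs = int(np.floor(fraction * idx.size))
    if n_hubs == 0:
        return []
    member_deg = avg_degree[idx]
    # stable sort on negated degree preserves member order among ties
    order = np.argsort(-member_deg, kind="stable")[:n_hubs]
    return [d.members[i] for i in order]


def subject_metrics(c: Connectome | np.ndarray) -> dict[str, np.ndarray | float]:
    """All nodal and global measures of one (sub)network."""
    w = _weights(c)
    k = degree_centrality(w)
    eloc = local_efficiency(w)
    return {
        "degree": k,
        "local_efficiency": eloc,
        "clustering": clustering_coefficient(w),
        "global_efficiency": global_efficiency(w) if w.shape[0] >= 2 else 0.0,
        "avg_local_efficiency": float(eloc.mean()),
        "avg_degree": float(k.mean()),
    }


def metric_table(
    subject_weights: dict[str, np.ndarray],
    networks: dict[str, np.ndarray],
    network_labels: dict[str, Sequence[str]],
    threshold: float,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format table of metrics per subject, network, node (and global).

    Parameters
    ----------
    subject_weights : dict subject_id -> (n, n) thresholded weight matrix
    networks : dict network name -> member index array into the full matrix
    network_labels : dict network name -> member labels (same order)
    threshold : SD-unit level the matrices were thresholded at (recorded)
    groups : optional dict subject_id -> group label
    """
    rows = []
    for sid, w in subject_weights.items():
        group = groups.get(sid) if groups else None
        for net, idx in networks.items():
            sub = w[np.ix_(idx, idx)]
            m = subject_metrics(sub)
            labels = network_labels[net]
            for name in GLOBAL_METRICS:
                rows.append(
                    (sid, group, net, threshold, "global", "", name, m[name])
                )
            for name in NODAL_METRICS:
                for label, value in zip(labels, m[name]):
                    rows.append(
                        (sid, group, net, threshold, "node", label, name, value)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "network", "threshold",
            "scope", "node", "metric", "value",
        ],
    )
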