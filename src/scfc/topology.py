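"""Weighted graph metrics of sparse functional networks.

All metrics follow the weighted-toolbox convention: edge weights are first
normalized by the matrix maximum (so the strongest edge has weight 1), edge
lengths are reciprocal weights, and shortest paths use Dijkstra over those
lengths.  Efficiencies are means of inverse distances with disconnected pairs
contributing zero, which bounds every efficiency in [0, 1] and keeps sparse
networks finite.  The characteristic path length defaults to the harmonic
convention ``Lp = 1 / Eglob`` (an ``"arithmetic"`` alternative averages the
finite distances only).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .io import ConnectivityMatrix, ValidationError
from .network import SparseNetwork, ThresholdScheme, sparsity_series
from .coupling import auc_summary

__all__ = [
    "TopologyProfile",
    "edge_lengths",
    "all_pairs_shortest",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "char_path_length",
    "topology_profile",
]


def _normalized_weights(w: np.ndarray) -> np.ndarray:
    mx = w.max()
    if mx <= 0.0:
        raise ValidationError("all-zero network has no defined edge lengths")
    return w / mx


def edge_lengths(net: SparseNetwork) -> np.ndarray:
    """Length matrix: 1 / (weight / max weight) on retained edges, inf off."""
    w = _normalized_weights(net.weights)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0.0, 1.0 / w, np.inf)
    np.fill_diagonal(lengths, np.inf)  # no self loops
    return lengths


def _distances_from_weights(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances from a (normalized) weight matrix."""
    n = w.shape[0]
    if w.max() <= 0.0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    wn = _normalized_weights(w)
    rows, cols = np.nonzero(np.triu(wn, k=1))
    lengths = 1.0 / wn[rows, cols]
    graph = csr_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    return dijkstra(graph, directed=False)


def all_pairs_shortest(net: SparseNetwork) -> np.ndarray:
    """Shortest-path distance matrix (inf for disconnected pairs)."""
    return _distances_from_weights(net.weights)


def _efficiency_from_distances(d: np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to the other nodes."""
    n = d.shape[0]
    inv = np.zeros_like(d)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(net: SparseNetwork) -> float:
    """Mean inverse shortest-path distance over ordered node pairs."""
    if net.n_regions < 2:
        raise ValidationError("need at least 2 nodes")
    d = all_pairs_shortest(net)
    return float(_efficiency_from_distances(d).mean())


def nodal_efficiency(net: SparseNetwork, node: int | str | None = None):
    """Mean inverse distance from one node (or all nodes) to the rest.

    With ``node=None`` returns the full per-node vector.
    """
    d = all_pairs_shortest(net)
    e = _efficiency_from_distances(d)
    if node is None:
        return e
    if isinstance(node, str):
        try:
            node = net.region_labels.index(node)
        except ValueError:
            raise ValidationError(f"unknown node {node!r}") from None
    if not (0 <= int(node) < net.n_regions):
        raise ValidationError(f"node index {node} out of range")
    return float(e[int(node)])


def local_efficiency(net: SparseNetwork) -> float:
    """Mean over nodes of the neighbour-subgraph global efficiency.

    The subgraph induced by each node's neighbours keeps the (normalized)
    weights of the full network; nodes with fewer than two neighbours
    contribute zero.
    """
    if net.n_regions < 2:
        raise ValidationError("need at least 2 nodes")
    w = _normalized_weights(net.weights)
    total = 0.0
    for i in range(net.n_regions):
        nbrs = np.nonzero(w[i] > 0.0)[0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        if sub.max() <= 0.0:
            continue
        d = _distances_from_weights_local(sub)
        total += float(_efficiency_from_distances(d).mean())
    return total / net.n_regions


def _distances_from_weights_local(sub: np.ndarray) -> np.ndarray:
    """Subgraph distances; weights are NOT re-normalized (lengths 1/w on the
    already max-normalized parent scale)."""
    n = sub.shape[0]
    rows, cols = np.nonzero(np.triu(sub, k=1))
    if len(rows) == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    lengths = 1.0 / sub[rows, cols]
    graph = csr_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    return dijkstra(graph, directed=False)


def char_path_length(net: SparseNetwork, convention: str = "harmonic") -> float:
    """Characteristic path length.

    ``"harmonic"`` (default): ``1 / Eglob`` — finite and monotone under
    disconnection, NaN when the network is edgeless.  ``"arithmetic"``:
    mean of the finite off-diagonal distances.
    """
    if convention not in ("harmonic", "arithmetic"):
        raise ValidationError(f"unknown Lp convention {convention!r}")
    d = all_pairs_shortest(net)
    if convention == "harmonic":
        eg = float(_efficiency_from_distances(d).mean())
        return 1.0 / eg if eg > 0 else float("nan")
    off = ~np.eye(net.n_regions, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


@dataclasses.dataclass(frozen=True)
class TopologyProfile:
    """Per-threshold global metrics and per-node efficiency for one subject.

    ``globals_table``: columns ``sparsity, Lp, Eglob, Eloc``.
    ``nodal_table``: columns ``sparsity, region, Enodal``.
    ``auc``: AUC per global metric; ``nodal_auc``: AUC per region.
    """

    subject_id: str
    scheme: ThresholdScheme
    globals_table: pd.DataFrame
    nodal_table: pd.DataFrame
    auc: dict[str, float]
    nodal_auc: dict[str, float]
    lp_convention: str = "harmonic"


def topology_profile(
    fc: ConnectivityMatrix,
    scheme: ThresholdScheme | None = None,
    subject_id: str = "",
    lp_convention: str = "harmonic",
    include_local: bool = True,
) -> TopologyProfile:
    """Compute Lp, Eglob, Eloc and per-node efficiency across the threshold
    series, with threshold-averaged AUC summaries."""
    scheme = scheme or ThresholdScheme.default()
    grows = []
    nrows = []
    for net in sparsity_series(fc, scheme):
        d = all_pairs_shortest(net)
        enod = _efficiency_from_distances(d)
        eg = float(enod.mean())
        el = local_efficiency(net) if include_local else float("nan")
        if lp_convention == "harmonic":
            lp = 1.0 / eg if eg > 0 else float("nan")
        else:
            lp = char_path_length(net, "arithmetic")
        grows.append((net.sparsity, lp, eg, el))
        for lab, e in zip(fc.region_labels, enod):
            nrows.append((net.sparsity, lab, float(e)))
    gt = pd.DataFrame(grows, columns=["sparsity", "Lp", "Eglob", "Eloc"])
    nt = pd.DataFrame(nrows, columns=["sparsity", "region", "Enodal"])
    auc = {}
    for metric in ("Lp", "Eglob", "Eloc"):
        try:
            auc[metric] = auc_summary(gt[metric].to_numpy(), scheme)
        except ValidationError:
            auc[metric] = float("nan")
    nodal_auc = {}
    for lab in fc.region_labels:
        vals = nt.loc[nt["region"] == lab, "Enodal"].to_numpy()
        try:
            nodal_auc[lab] = auc_summary(vals, scheme)
        except ValidationError:
            nodal_auc[lab] = float("nan")
    return TopologyProfile(subject_id, scheme, gt, nt, auc, nodal_auc, lp_convention)
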