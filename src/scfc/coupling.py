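"""Structural-functional connectivity (SC-FC) coupling.

The coupling statistic is the Pearson correlation between the vector of
nonzero FC edge weights surviving a proportional sparsity threshold and the
vector of the same edges' SC weights.  It is computed for the whole brain and
restricted to within-module edge sets, at every sparsity of a threshold
series, and summarized across the series by a threshold-averaged AUC
(trapezoidal integral divided by the sparsity range, so the summary shares
the statistic's scale).

Undefined values (fewer than three edges in scope, or zero variance in either
vector) are carried as NaN; the AUC tolerates and linearly interpolates at
most 10% undefined points per scope.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ConnectivityMatrix, ModulePartition, ValidationError
from .network import SparseNetwork, ThresholdScheme, edge_order, _edge_count, _from_prefix

__all__ = [
    "CouplingProfile",
    "WHOLE_BRAIN",
    "couple_edges",
    "whole_brain_coupling",
    "modular_coupling",
    "coupling_profile",
    "auc_summary",
]

WHOLE_BRAIN = "whole_brain"

#: minimum number of edges for a defined coupling value
MIN_EDGES = 3
#: maximum fraction of undefined points the AUC will interpolate over
MAX_UNDEFINED_FRACTION = 0.10


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(xd @ xd)
    sy = np.sqrt(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xd @ yd) / (sx * sy), -1.0, 1.0))


def couple_edges(
    fc_sparse: SparseNetwork,
    sc: ConnectivityMatrix,
    edge_set: np.ndarray | Sequence[tuple[int, int]],
) -> float:
    """Pearson r between surviving FC weights and their SC counterparts.

    ``edge_set`` must be a subset of the sparse network's retained edges
    (as ``(i, j)`` index pairs with ``i < j``).  SC zeros are included as-is;
    no structural-edge filtering is applied.  Returns NaN when fewer than
    three edges are in scope or either vector is constant.
    """
    if fc_sparse.region_labels != sc.region_labels:
        raise ValidationError("FC and SC region labels differ or are misordered")
    edges = np.asarray(edge_set, dtype=int).reshape(-1, 2)
    retained = set(map(tuple, fc_sparse.edges))
    bad = [tuple(e) for e in edges if tuple(e) not in retained]
    if bad:
        raise ValidationError(f"edges not retained at this sparsity: {bad[:5]}")
    if edges.shape[0] < MIN_EDGES:
        return float("nan")
    fc_vals = fc_sparse.weights[edges[:, 0], edges[:, 1]]
    sc_vals = sc.weights[edges[:, 0], edges[:, 1]]
    return _pearson(fc_vals, sc_vals)


def whole_brain_coupling(fc_sparse: SparseNetwork, sc: ConnectivityMatrix) -> float:
    """Coupling over all retained edges of the sparse functional network."""
    return couple_edges(fc_sparse, sc, fc_sparse.edges)


def modular_coupling(
    fc_sparse: SparseNetwork,
    sc: ConnectivityMatrix,
    partition: ModulePartition,
    module_name: str,
) -> float:
    """Coupling over retained edges with both endpoints inside one module."""
    if module_name not in partition.module_names:
        raise ValidationError(f"unknown module {module_name!r}")
    idx = partition.indices(fc_sparse.region_labels)[module_name]
    member = np.zeros(fc_sparse.n_regions, dtype=bool)
    member[idx] = True
    e = fc_sparse.edges
    mask = member[e[:, 0]] & member[e[:, 1]]
    return couple_edges(fc_sparse, sc, e[mask])


@dataclasses.dataclass(frozen=True)
class CouplingProfile:
    """Per-threshold coupling values and AUC summaries for one subject.

    ``table`` is long-format with columns ``scope, sparsity, r, n_edges``;
    ``auc`` maps each scope (``whole_brain`` plus module names) to its
    threshold-averaged AUC (NaN when more than 10% of points are undefined).
    """

    subject_id: str
    scheme: ThresholdScheme
    table: pd.DataFrame
    auc: dict[str, float]

    def values(self, scope: str) -> np.ndarray:
        sub = self.table[self.table["scope"] == scope].sort_values("sparsity")
        return sub["r"].to_numpy()


def coupling_profile(
    fc: ConnectivityMatrix,
    sc: ConnectivityMatrix,
    partition: ModulePartition,
    scheme: ThresholdScheme | None = None,
    subject_id: str = "",
) -> CouplingProfile:
    """Whole-brain and per-module coupling at every sparsity, plus AUCs.

    The FC edge ranking is computed once and reused across the (nested)
    threshold series.
    """
    scheme = scheme or ThresholdScheme.default()
    if fc.region_labels != sc.region_labels:
        raise ValidationError("FC and SC region labels differ or are misordered")
    partition.validate_against(fc.region_labels)

    iu, ju, order = edge_order(fc)
    idx = partition.indices(fc.region_labels)
    member = {}
    for m, ix in idx.items():
        flag = np.zeros(fc.n_regions, dtype=bool)
        flag[ix] = True
        member[m] = flag

    scopes = [WHOLE_BRAIN, *partition.module_names]
    rows = []
    for s in scheme.values:
        k = _edge_count(s, fc.n_regions)
        net = _from_prefix(fc, iu, ju, order, k, s)
        e = net.edges
        fc_vals = net.weights[e[:, 0], e[:, 1]]
        sc_vals = sc.weights[e[:, 0], e[:, 1]]
        rows.append((WHOLE_BRAIN, s, _r_or_nan(fc_vals, sc_vals), len(e)))
        for m in partition.module_names:
            mask = member[m][e[:, 0]] & member[m][e[:, 1]]
            rows.append(
                (m, s, _r_or_nan(fc_vals[mask], sc_vals[mask]), int(mask.sum()))
            )
    table = pd.DataFrame(rows, columns=["scope", "sparsity", "r", "n_edges"])
    auc = {}
    for scope in scopes:
        vals = table.loc[table["scope"] == scope, "r"].to_numpy()
        try:
            auc[scope] = auc_summary(vals, scheme)
        except ValidationError:
            auc[scope] = float("nan")
    return CouplingProfile(subject_id, scheme, table, auc)


def _r_or_nan(fc_vals: np.ndarray, sc_vals: np.ndarray) -> float:
    if len(fc_vals) < MIN_EDGES:
        return float("nan")
    return _pearson(fc_vals, sc_vals)


def auc_summary(values: Sequence[float], scheme: ThresholdScheme) -> float:
    """Threshold-averaged AUC of a per-threshold metric series.

    Trapezoidal integral over the sparsity grid divided by the grid span, so
    a constant series returns the constant.  Up to 10% undefined (NaN) points
    are filled by linear interpolation from neighbouring defined points
    (nearest defined value at the ends); more missingness, fewer than two
    defined points, or a single-point scheme with an undefined value raise.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(scheme.values, dtype=float)
    if v.shape != s.shape:
        raise ValidationError(
            f"series length {v.shape} does not match scheme length {s.shape}"
        )
    defined = np.isfinite(v)
    if len(v) == 1:
        if not defined[0]:
            raise ValidationError("single-point series is undefined")
        return float(v[0])
    if defined.sum() < 2:
        raise ValidationError("need at least 2 defined points for AUC")
    if (~defined).sum() > MAX_UNDEFINED_FRACTION * len(v):
        raise ValidationError(
            f"{(~defined).sum()}/{len(v)} points undefined exceeds "
            f"{MAX_UNDEFINED_FRACTION:.0%} interpolation budget"
        )
    if not defined.all():
        v = v.copy()
        v[~defined] = np.interp(s[~defined], s[defined], v[defined])
    return float(np.trapezoid(v, s) / (s[-1] - s[0]))
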