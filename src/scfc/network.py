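"""Functional/structural network construction and proportional thresholding.

Functional networks are Pearson-correlation matrices of region-averaged time
series (absolute-value convention on by default); structural networks are
symmetrized tractography connection-probability matrices.  Sparsification
keeps a fixed fraction of the strongest upper-triangle edges — the sparsity
threshold — swept over a series (default 8%..60% in 2% steps) so no single
threshold choice drives downstream statistics.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Sequence

import numpy as np

from .io import ConnectivityMatrix, TimeSeriesMatrix, ValidationError

__all__ = [
    "ThresholdScheme",
    "SparseNetwork",
    "build_fc",
    "symmetrize_sc",
    "threshold_proportional",
    "sparsity_series",
    "edge_order",
    "round_half_away",
]


@dataclasses.dataclass(frozen=True)
class ThresholdScheme:
    """An ordered series of sparsity fractions (retained strongest edges)."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.values)
        object.__setattr__(self, "values", v)
        if len(v) == 0:
            raise ValidationError("threshold scheme is empty")
        if any(not (0.0 < x <= 1.0) for x in v):
            raise ValidationError("sparsity values must lie in (0, 1]")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValidationError("sparsity values must be strictly increasing")

    @classmethod
    def default(cls) -> "ThresholdScheme":
        """8% to 60% in 2% steps — 27 sparsity levels."""
        return cls(tuple(round(0.08 + 0.02 * k, 2) for k in range(27)))

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "ThresholdScheme":
        n = int(round((hi - lo) / step)) + 1
        return cls(tuple(round(lo + step * k, 10) for k in range(n)))

    def __len__(self) -> int:
        return len(self.values)

    @property
    def span(self) -> float:
        return self.values[-1] - self.values[0]


@dataclasses.dataclass(frozen=True)
class SparseNetwork:
    """A proportionally thresholded network.

    ``weights`` is symmetric with zeros off the retained edge set;
    ``edges`` lists retained upper-triangle pairs ``(i, j)`` with ``i < j``.
    """

    region_labels: tuple[str, ...]
    weights: np.ndarray
    sparsity: float
    edges: np.ndarray  # (k, 2) int array, i < j

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_weights(self) -> np.ndarray:
        return self.weights[self.edges[:, 0], self.edges[:, 1]]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def build_fc(ts: TimeSeriesMatrix, absolute: bool = True) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of region time series.

    With ``absolute=True`` (the default convention) the matrix holds |r|;
    otherwise signed r.  The diagonal is zeroed either way.
    """
    constant = ts.constant_regions()
    if constant:
        raise ValidationError(f"constant time series for regions: {constant}")
    r = np.corrcoef(ts.samples)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    if absolute:
        r = np.abs(r)
    r = (r + r.T) / 2.0  # exact symmetry against fp asymmetry
    return ConnectivityMatrix(ts.region_labels, r, "functional")


def symmetrize_sc(
    w: np.ndarray, region_labels: Sequence[str] | None = None
) -> ConnectivityMatrix:
    """Average a (possibly direction-dependent) nonnegative matrix with its
    transpose and zero the diagonal."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"matrix must be square, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValidationError("matrix contains non-finite values")
    if w.min() < 0:
        raise ValidationError("structural weights must be nonnegative")
    sym = (w + w.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    if region_labels is None:
        region_labels = [f"R{i + 1:02d}" for i in range(w.shape[0])]
    return ConnectivityMatrix(tuple(region_labels), sym, "structural")


def edge_order(c: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight.

    Ties are broken by ascending ``(row, col)`` index, which makes the
    threshold series nested and deterministic.  Returns ``(rows, cols, order)``
    where ``order`` indexes into the flattened upper triangle.
    """
    iu, ju = np.triu_indices(c.n_regions, k=1)
    w = c.weights[iu, ju]
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -w))
    return iu, ju, order


def _edge_count(s: float, n: int) -> int:
    total = n * (n - 1) // 2
    k = round_half_away(s * total)
    if k == 0:
        raise ValidationError(
            f"sparsity {s:g} retains zero edges for n={n}; increase sparsity"
        )
    return min(k, total)


def threshold_proportional(c: ConnectivityMatrix, s: float) -> SparseNetwork:
    """Keep the ``round(s * n(n-1)/2)`` strongest upper-triangle edges.

    Rounding is half-away-from-zero; ties at the cut are resolved by ascending
    ``(row, col)`` index so repeated runs and nested thresholds agree.
    """
    if not (0.0 < s <= 1.0):
        raise ValidationError(f"sparsity must be in (0, 1], got {s}")
    iu, ju, order = edge_order(c)
    k = _edge_count(s, c.n_regions)
    return _from_prefix(c, iu, ju, order, k, s)


def _from_prefix(
    c: ConnectivityMatrix,
    iu: np.ndarray,
    ju: np.ndarray,
    order: np.ndarray,
    k: int,
    s: float,
) -> SparseNetwork:
    keep = order[:k]
    rows, cols = iu[keep], ju[keep]
    w = np.zeros_like(c.weights)
    w[rows, cols] = c.weights[rows, cols]
    w[cols, rows] = c.weights[rows, cols]
    edges = np.column_stack([rows, cols])
    return SparseNetwork(c.region_labels, w, float(s), edges)


def sparsity_series(
    c: ConnectivityMatrix, scheme: ThresholdScheme
) -> Iterator[SparseNetwork]:
    """Yield the thresholded network at each sparsity of ``scheme``.

    The edge ranking is computed once; successive networks are nested.
    """
    iu, ju, order = edge_order(c)
    for s in scheme.values:
        k = _edge_count(s, c.n_regions)
        yield _from_prefix(c, iu, ju, order, k, s)
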