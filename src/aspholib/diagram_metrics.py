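"""Distances between persistence diagrams, and diagram modifications.

Matching semantics
------------------
Both metrics optimise over partial matchings in which every unmatched
diagram point is paired with its orthogonal projection onto the diagonal
{death = birth}.  The cost of a matched pair is the L-infinity distance
between the two points; the cost of a diagonal assignment is the
L-infinity distance to the diagonal, |death - birth| / 2.  This diagonal
augmentation is what makes the distances well defined for diagrams of
unequal cardinality -- which is the generic case here, since conjugated
clouds always differ by one dimension-0 class.

Bottleneck minimises the maximum pair cost; Wasserstein of order p >= 1
minimises the p-norm of the pair costs.  Consequently
``bottleneck(X, Y) <= wasserstein(X, Y, p=1)`` always.

Diagram modifications
---------------------
Rotating the diagram plane (30 or 60 degrees) or reflecting it across
the diagonal changes the distance of each point to the matching boundary
and lets downstream models weight short-persistence classes differently.
"Y-axis rotated clockwise by theta" is implemented as a counterclockwise
rotation of the points about the origin; after a transform the diagonal
cost remains |d - b| / 2, regardless of which side of the diagonal the
point lands on.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .persistence import PersistenceDiagram

IDENTITY = "identity"
ROTATE30 = "rotate30"
ROTATE60 = "rotate60"
REFLECT_DIAGONAL = "reflect_diagonal"

TRANSFORMS = (IDENTITY, ROTATE30, ROTATE60, REFLECT_DIAGONAL)

_ANGLES = {ROTATE30: np.pi / 6, ROTATE60: np.pi / 3}


def _points(diagram) -> np.ndarray:
    pts = getattr(diagram, "intervals", diagram)
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def transform_diagram(diagram, transform: str):
    """Apply a plane transform to every diagram point.

    Accepts a ``PersistenceDiagram`` (returned as such) or a bare (n, 2)
    array.  Coordinates must be finite: cap essential classes first.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform: {transform!r}")
    pts = _points(diagram)
    if not np.all(np.isfinite(pts)):
        raise ValueError("diagram coordinates must be finite")
    if transform == IDENTITY:
        out = pts.copy()
    elif transform == REFLECT_DIAGONAL:
        out = pts[:, ::-1].copy()
    else:
        theta = _ANGLES[transform]
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        out = pts @ rot.T
    if isinstance(diagram, PersistenceDiagram):
        return PersistenceDiagram(diagram.dim, out, diagram.max_filtration)
    return out


def _diagonal_costs(pts: np.ndarray) -> np.ndarray:
    return np.abs(pts[:, 1] - pts[:, 0]) / 2.0


def _augmented_cost_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(n+m) x (n+m) cost matrix with diagonal-projection slots.

    Row i < n is point x_i; rows >= n are diagonal slots for the points of
    Y (and symmetrically for columns).  Diagonal-to-diagonal costs are 0.
    """
    n, m = len(x), len(y)
    cost = np.zeros((n + m, n + m))
    if n and m:
        cost[:n, :m] = np.max(
            np.abs(x[:, None, :] - y[None, :, :]), axis=2)
    cost[:n, m:] = _diagonal_costs(x)[:, None]
    cost[n:, :m] = _diagonal_costs(y)[None, :]
    return cost


def wasserstein(x_diagram, y_diagram, p: float = 1.0) -> float:
    """Wasserstein distance of order p between two diagrams.

    Minimises ``(sum of matched L-inf costs**p)**(1/p)`` over diagonal-
    augmented matchings, via an exact linear assignment.
    """
    if p < 1:
        raise ValueError("Wasserstein order p must be >= 1")
    x, y = _points(x_diagram), _points(y_diagram)
    if len(x) == 0 and len(y) == 0:
        return 0.0
    cost = _augmented_cost_matrix(x, y) ** p
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() ** (1.0 / p))


def bottleneck(x_diagram, y_diagram) -> float:
    """Bottleneck distance: minimax cost over augmented matchings.

    Computed exactly by a binary search over the candidate costs, testing
    feasibility with a maximum bipartite matching.
    """
    x, y = _points(x_diagram), _points(y_diagram)
    if len(x) == 0 and len(y) == 0:
        return 0.0
    cost = _augmented_cost_matrix(x, y)
    candidates = np.unique(cost)
    lo, hi = 0, len(candidates) - 1

    def feasible(t: float) -> bool:
        mask = cost <= t
        graph = csr_matrix(mask)
        match = maximum_bipartite_matching(graph, perm_type="column")
        return int((match >= 0).sum()) == cost.shape[0]

    if feasible(candidates[lo]):
        return float(candidates[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if feasible(candidates[mid]):
            hi = mid
        else:
            lo = mid
    return float(candidates[hi])
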