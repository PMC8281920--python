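"""Vietoris-Rips persistent homology over Z2.

Two independent computations live here:

``rips_persistence``
    The production path: persistent cohomology with the clearing
    optimisation.  Dimension-0 pairs come from a union-find sweep over the
    sorted edges; higher pairs from a column reduction of the coboundary
    matrices, processing simplices in reverse filtration order with sparse
    (set-based) columns.  This is the standard scheme that makes
    matrix-reduction persistence tractable for Rips-type complexes.

``reduce_boundary_matrix``
    A deliberately naive textbook reduction of the full Z2 boundary matrix,
    enumerating every simplex of the filtration explicitly.  It is only
    meant for small clouds (<= ~10 points) and serves as the independent
    oracle that pins down the contract of the production path.

Both report essential classes with ``death`` equal to the filtration cap,
never as infinities: downstream diagram metrics need finite coordinates,
and the conjugated-cloud construction guarantees a dimension-0 essential
class in every diagram.  Intervals with ``birth == death`` carry no metric
information and are dropped on output (they sit on the diagonal, at
distance zero from it).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) intervals for one homology dimension.

    ``intervals`` is an (n, 2) float array; essential classes carry
    ``death == max_filtration``.
    """

    dim: int
    intervals: np.ndarray
    max_filtration: float

    def __post_init__(self):
        arr = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def births(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def persistences(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def long_intervals(self, threshold: float) -> np.ndarray:
        """Intervals with persistence strictly greater than ``threshold``."""
        return self.intervals[self.persistences > threshold]


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("filtration matrix must be square")
    if not np.allclose(m, m.T, rtol=0.0, atol=0.0):
        raise ValueError("filtration matrix must be exactly symmetric")
    if np.any(m < 0):
        raise ValueError("filtration matrix entries must be non-negative")
    if np.any(np.diag(m) != 0):
        raise ValueError("filtration matrix diagonal must be zero")
    return m


def _sorted_edges(m: np.ndarray, cap: float):
    n = m.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = m[iu, ju]
    keep = w <= cap
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))
    return iu[order], ju[order], w[order]


def _h0_union_find(n: int, iu, ju, w, cap: float):
    """Dimension-0 pairs and the set of component-merging edges."""
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bars = []
    merge_edge = np.zeros(len(w), dtype=bool)
    for e in range(len(w)):
        a, b = find(int(iu[e])), find(int(ju[e]))
        if a != b:
            parent[max(a, b)] = min(a, b)
            bars.append((0.0, float(w[e])))
            merge_edge[e] = True
    n_components = sum(1 for x in range(n) if find(x) == x)
    bars.extend((0.0, cap) for _ in range(n_components))
    return bars, merge_edge


def rips_persistence(
    matrix,
    max_dim: int = 1,
    cap: float | None = None,
    drop_zero: bool = True,
) -> list[PersistenceDiagram]:
    """Persistent homology of the VR filtration of a symmetric matrix.

    Parameters
    ----------
    matrix
        Symmetric non-negative matrix with zero diagonal (a
        ``FiltrationMatrix`` from :mod:`aspholib.filtration` or a bare
        array).  A simplex enters the filtration at the maximum of its
        pairwise entries; only simplices with value <= ``cap`` exist.
    max_dim
        Highest homology dimension computed (0, 1 or 2).
    cap
        Filtration cap; defaults to the matrix's ``max_filtration``
        attribute, else the largest entry.  Essential classes die at the
        cap.
    drop_zero
        Drop intervals with ``birth == death`` (the default; they are
        metrically invisible).

    Returns
    -------
    list of ``PersistenceDiagram``, one per dimension ``0..max_dim``.
    """
    if max_dim not in (0, 1, 2):
        raise ValueError("max_dim must be 0, 1 or 2")
    values = getattr(matrix, "values", matrix)
    m = _validate_matrix(values)
    if cap is None:
        cap = getattr(matrix, "max_filtration", None)
        if cap is None:
            cap = float(m.max()) if m.size else 0.0
    cap = float(cap)
    n = m.shape[0]

    iu, ju, w = _sorted_edges(m, cap)
    bars0, merge_edge = _h0_union_find(n, iu, ju, w, cap)
    diagrams = [bars0, [], []]

    if max_dim >= 1 and n >= 2:
        _higher_pairs(m, cap, iu, ju, w, merge_edge, max_dim, diagrams)

    out = []
    for dim in range(max_dim + 1):
        bars = np.array(diagrams[dim], dtype=float).reshape(-1, 2)
        if drop_zero and len(bars):
            bars = bars[bars[:, 1] > bars[:, 0]]
        out.append(PersistenceDiagram(dim, bars, cap))
    return out


def _higher_pairs(m, cap, iu, ju, w, merge_edge, max_dim, diagrams):
    """Dimension 1 (and 2) pairs via coboundary reduction with clearing."""
    n = m.shape[0]
    adj = m <= cap
    np.fill_diagonal(adj, False)
    nbrs = [np.flatnonzero(adj[i]) for i in range(n)]

    # triangles, sorted by (filtration value, lexicographic vertices)
    tris = []
    for e in range(len(w)):
        i, j = int(iu[e]), int(ju[e])
        cn = nbrs[j][adj[i][nbrs[j]]]
        for k in cn[cn > j]:
            k = int(k)
            tris.append((max(m[i, j], m[i, k], m[j, k]), i, j, k))
    tris.sort()
    nt = len(tris)
    tri_w = np.array([t[0] for t in tris]) if tris else np.empty(0)
    tri_idx = {(i * n + j) * n + k: s for s, (_, i, j, k) in enumerate(tris)}

    # H1: columns are the coboundaries of cycle-creating edges, processed in
    # reverse filtration order; the pivot of a column is its earliest
    # triangle cofacet.  Component-killing edges are cleared (they are
    # pivots of the dimension-0 pairing and reduce to zero).
    tri_death = np.zeros(nt, dtype=bool)
    low: dict[int, set] = {}
    for e in range(len(w) - 1, -1, -1):
        if merge_edge[e]:
            continue
        i, j = int(iu[e]), int(ju[e])
        col = set()
        for k in nbrs[i]:
            if adj[j, k]:
                a, b, c = sorted((i, j, int(k)))
                col.add(tri_idx[(a * n + b) * n + c])
        while col:
            p = min(col)
            if p in low:
                col ^= low[p]
            else:
                low[p] = col
                tri_death[p] = True
                diagrams[1].append((float(w[e]), float(tri_w[p])))
                break
        if not col:
            diagrams[1].append((float(w[e]), cap))

    if max_dim < 2:
        return

    tri_v = np.array([t[1:] for t in tris], dtype=np.int64) \
        if tris else np.empty((0, 3), np.int64)
    tets = []
    for s in range(nt):
        i, j, k = map(int, tri_v[s])
        cn = np.flatnonzero(adj[i] & adj[j] & adj[k])
        for l in cn[cn > k]:
            l = int(l)
            tets.append((max(tri_w[s], m[i, l], m[j, l], m[k, l]), i, j, k, l))
    tets.sort()
    tet_w = np.array([t[0] for t in tets]) if tets else np.empty(0)
    tet_idx = {((i * n + j) * n + k) * n + l: s
               for s, (_, i, j, k, l) in enumerate(tets)}

    # H2: same scheme one dimension up; triangles already paired as
    # dimension-1 deaths are cleared.
    low = {}
    for s in range(nt - 1, -1, -1):
        if tri_death[s]:
            continue
        i, j, k = map(int, tri_v[s])
        col = set()
        for l in nbrs[i]:
            if adj[j, l] and adj[k, l]:
                a, b, c, d = sorted((i, j, k, int(l)))
                col.add(tet_idx[((a * n + b) * n + c) * n + d])
        while col:
            p = min(col)
            if p in low:
                col ^= low[p]
            else:
                low[p] = col
                diagrams[2].append((float(tri_w[s]), float(tet_w[p])))
                break
        if not col:
            diagrams[2].append((float(tri_w[s]), cap))


# ---------------------------------------------------------------------------
# Explicit boundary-matrix oracle
# ---------------------------------------------------------------------------

@dataclass
class BoundaryMatrixOracle:
    """Fully enumerated VR filtration with its Z2 boundary matrix.

    Simplices are stored in a single global filtration order: sorted by
    (value, dimension, vertex tuple), which guarantees every face precedes
    its cofaces.  Columns are Python integers used as Z2 bit-vectors over
    the rows (all preceding simplices).  Intended for small instances only.
    """

    simplices: list = field(default_factory=list)   # (value, dim, verts)
    columns: list = field(default_factory=list)     # bigint boundary columns
    max_filtration: float = 0.0

    @classmethod
    def from_matrix(cls, matrix, max_dim: int, cap: float | None = None):
        values = getattr(matrix, "values", matrix)
        m = _validate_matrix(values)
        if cap is None:
            cap = getattr(matrix, "max_filtration", None)
            if cap is None:
                cap = float(m.max()) if m.size else 0.0
        cap = float(cap)
        n = m.shape[0]
        if n > 16:
            raise ValueError("oracle is for small clouds only (n <= 16)")
        simplices = []
        for dim in range(max_dim + 2):
            for verts in itertools.combinations(range(n), dim + 1):
                if dim == 0:
                    value = 0.0
                else:
                    value = max(m[a, b] for a, b in
                                itertools.combinations(verts, 2))
                if value <= cap:
                    simplices.append((float(value), dim, verts))
        simplices.sort()
        index = {s[2]: idx for idx, s in enumerate(simplices)}
        columns = []
        for value, dim, verts in simplices:
            col = 0
            if dim > 0:
                for omit in range(dim + 1):
                    face = verts[:omit] + verts[omit + 1:]
                    col |= 1 << index[face]
            columns.append(col)
        oracle = cls(simplices, columns, cap)
        oracle._check_filtration_order()
        return oracle

    def _check_filtration_order(self):
        index = {s[2]: idx for idx, s in enumerate(self.simplices)}
        for idx, (_, dim, verts) in enumerate(self.simplices):
            if dim == 0:
                continue
            for omit in range(dim + 1):
                face = verts[:omit] + verts[omit + 1:]
                assert index[face] < idx, "face must precede coface"

    def boundary_of_boundary_is_zero(self) -> bool:
        """Check the fundamental identity on every column, over Z2."""
        for col in self.columns:
            acc = 0
            rows = col
            while rows:
                r = rows & -rows
                acc ^= self.columns[r.bit_length() - 1]
                rows ^= r
            if acc != 0:
                return False
        return True


def reduce_boundary_matrix(
    oracle: BoundaryMatrixOracle,
    max_dim: int | None = None,
    drop_zero: bool = True,
) -> list[PersistenceDiagram]:
    """Textbook left-to-right column reduction of the Z2 boundary matrix.

    Pivot pairings give the persistence pairs; unpaired creators of
    dimension <= ``max_dim`` become essential classes dying at the cap.
    Exact multiset agreement with :func:`rips_persistence` (after dropping
    zero-persistence intervals) is the correctness contract of the
    production path.
    """
    simplices = oracle.simplices
    if max_dim is None:
        max_dim = max(dim for _, dim, _ in simplices) - 1
    cap = oracle.max_filtration
    low: dict[int, int] = {}       # pivot row -> reduced column value
    creator = [False] * len(simplices)
    bars: dict[int, list] = {d: [] for d in range(max_dim + 1)}
    for j, col in enumerate(oracle.columns):
        while col:
            p = col.bit_length() - 1
            if p in low:
                col ^= low[p]
            else:
                low[p] = col
                creator[p] = False
                birth_val, birth_dim, _ = simplices[p]
                death_val = simplices[j][0]
                if birth_dim <= max_dim:
                    bars[birth_dim].append((birth_val, death_val))
                break
        if col == 0:
            creator[j] = True
    paired = set(low.keys())
    for j, (value, dim, _) in enumerate(simplices):
        if creator[j] and j not in paired and dim <= max_dim:
            bars[dim].append((value, cap))
    out = []
    for dim in range(max_dim + 1):
        arr = np.array(bars[dim], dtype=float).reshape(-1, 2)
        if drop_zero and len(arr):
            arr = arr[arr[:, 1] > arr[:, 0]]
        out.append(PersistenceDiagram(dim, arr, cap))
    return out


# ---------------------------------------------------------------------------
# Diagram serialization (plain text, columns: dim birth death)
# ---------------------------------------------------------------------------

def write_diagrams(diagrams: list[PersistenceDiagram], path) -> None:
    with open(path, "w") as fh:
        fh.write("dim,birth,death\n")
        for dgm in diagrams:
            for b, d in dgm.intervals:
                fh.write(f"{dgm.dim},{float(b)!r},{float(d)!r}\n")


def read_diagrams(path, max_filtration: float,
                  max_dim: int | None = None) -> list[PersistenceDiagram]:
    """Read diagrams written by :func:`write_diagrams`.

    An ``inf`` death is legal on input and replaced by the cap.  Pass
    ``max_dim`` to pad with empty diagrams for dimensions the file does
    not mention.
    """
    per_dim: dict[int, list] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "dim,birth,death":
            raise ValueError(f"unrecognised diagram header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            d, b, dd = line.split(",")
            death = float(dd)
            if np.isinf(death):
                death = max_filtration
            per_dim.setdefault(int(d), []).append((float(b), death))
    dims = max(per_dim) if per_dim else 0
    if max_dim is not None:
        dims = max(dims, max_dim)
    return [
        PersistenceDiagram(dim,
                           np.array(per_dim.get(dim, []), float).reshape(-1, 2),
                           max_filtration)
        for dim in range(dims + 1)
    ]
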