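"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def _pair_cost(a, b) -> float:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def _diag_cost(a) -> float:
    return abs(a[1] - a[0]) / 2.0


def brute_force_matching_distances(x, y, p: float = 1.0):
    """Exhaustive optimum over all diagonal-augmented matchings.

    Enumerates every subset of X matched injectively onto a subset of Y
    (all remaining points of either diagram projected to the diagonal)
    and returns (bottleneck, wasserstein_p).  Exponential: use only for
    diagrams of a few points.
    """
    x = np.asarray(x, float).reshape(-1, 2)
    y = np.asarray(y, float).reshape(-1, 2)
    n, m = len(x), len(y)
    best_max = np.inf
    best_sum = np.inf
    for k in range(min(n, m) + 1):
        for xs in combinations(range(n), k):
            for ys in permutations(range(m), k):
                costs = [_pair_cost(x[i], y[j]) for i, j in zip(xs, ys)]
                costs += [_diag_cost(x[i]) for i in range(n) if i not in xs]
                costs += [_diag_cost(y[j]) for j in range(m) if j not in ys]
                if costs:
                    best_max = min(best_max, max(costs))
                    best_sum = min(best_sum,
                                   sum(c ** p for c in costs))
                else:
                    best_max = 0.0
                    best_sum = 0.0
    return best_max, best_sum ** (1.0 / p)


def random_diagram(rng, max_points: int = 5) -> np.ndarray:
    """Random finite diagram with death >= birth."""
    k = rng.integers(0, max_points + 1)
    birth = rng.uniform(0, 1, size=k)
    death = birth + rng.uniform(0, 1, size=k)
    return np.column_stack([birth, death])


def diagrams_equal(dgm_a, dgm_b, atol: float = 1e-9) -> bool:
    """Multiset equality of two interval arrays up to ``atol``."""
    a = np.asarray(dgm_a, float).reshape(-1, 2)
    b = np.asarray(dgm_b, float).reshape(-1, 2)
    if a.shape != b.shape:
        return False
    a = a[np.lexsort((a[:, 1], a[:, 0]))]
    b = b[np.lexsort((b[:, 1], b[:, 0]))]
    return np.allclose(a, b, atol=atol, rtol=0.0)
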