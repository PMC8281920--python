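"""Filtration matrices for Vietoris-Rips persistence.

Two filtrations are supported: plain Euclidean distances, and the
correlation-kernel filtration in which atom pairs are assigned the value

    M[n, m] = 1 - Phi(||r_n - r_m||; parameters)

for a radial basis function Phi that equals 1 at zero separation and
decays monotonically with distance.  Two kernel families are provided:

* exponential: Phi(d; eta, kappa) = exp(-(d/eta)^kappa)
* lorentz:     Phi(d; eta, nu)    = 1 / (1 + (d/eta)^nu)

``eta`` is the length scale in Angstrom and the power (kappa or nu)
controls the decay sharpness; both must be positive.  Kernel filtration
values live in [0, 1), so kernel filtrations are capped at 1; the
Euclidean filtration is capped at the cloud cutoff radius by default.
Because 1 - Phi is a strictly increasing function of distance, the two
filtrations induce the same ordering of simplex insertions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

EXPONENTIAL = "exponential"
LORENTZ = "lorentz"


@dataclass(frozen=True)
class KernelSpec:
    """Radial basis kernel: family, length scale eta (A), decay power."""

    family: str
    eta: float
    power: float

    def __post_init__(self):
        if self.family not in (EXPONENTIAL, LORENTZ):
            raise ValueError(f"unknown kernel family: {self.family!r}")
        if not self.eta > 0:
            raise ValueError("kernel eta must be positive")
        if not self.power > 0:
            raise ValueError("kernel power must be positive")


#: Kernel parameter sets used for the production features (eta in
#: Angstrom): a long-range Lorentz kernel and a unit-power exponential.
DEFAULT_LORENTZ = KernelSpec(LORENTZ, eta=21.0, power=5.0)
DEFAULT_EXPONENTIAL = KernelSpec(EXPONENTIAL, eta=10.0, power=1.0)


@dataclass(frozen=True)
class FiltrationMatrix:
    """Symmetric pairwise filtration values with a finite cap.

    ``kind`` is ``"euclidean"`` (entries are distances, cap = cutoff) or
    ``"kernel"`` (entries are 1 - Phi in [0, 1], cap = 1).
    """

    values: np.ndarray
    kind: str
    max_filtration: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def kernel_value(distance, spec: KernelSpec):
    """Correlation Phi(d) in (0, 1]; equal to 1 at d = 0.

    Accepts scalars or arrays; negative distances are rejected.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    scaled = (d / spec.eta) ** spec.power
    if spec.family == EXPONENTIAL:
        out = np.exp(-scaled)
    else:
        out = 1.0 / (1.0 + scaled)
    return out if out.ndim else float(out)


def _pairwise(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    if len(pts) == 0:
        raise ValueError("need at least one point")
    return squareform(pdist(pts)) if len(pts) > 1 else np.zeros((1, 1))


def euclidean_matrix(points, cap: float) -> FiltrationMatrix:
    """Euclidean distance filtration, capped at ``cap`` (typically r_c)."""
    return FiltrationMatrix(_pairwise(points), "euclidean", float(cap))


def kernel_filtration_matrix(points, spec: KernelSpec) -> FiltrationMatrix:
    """Kernel correlation filtration M = 1 - Phi, capped at 1.

    Coincident points get entry 0 (full correlation), which is legal.
    """
    dist = _pairwise(points)
    values = 1.0 - kernel_value(dist, spec)
    np.fill_diagonal(values, 0.0)
    return FiltrationMatrix(values, "kernel", 1.0)


def kernel_matrix_from_distances(dist: np.ndarray, spec: KernelSpec) -> FiltrationMatrix:
    """Kernel filtration from a precomputed distance matrix.

    Avoids recomputing pairwise distances when the same cloud is swept
    over many kernel parameter sets (the image features do exactly that).
    """
    values = 1.0 - kernel_value(dist, spec)
    np.fill_diagonal(values, 0.0)
    return FiltrationMatrix(values, "kernel", 1.0)
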