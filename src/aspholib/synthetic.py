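"""Synthetic test inputs: manifold samples and pseudo-proteins.

Everything downstream is exercised without any external download:

* **Manifold samples** (circle, sphere, torus) with known Betti numbers
  provide ground truth for the persistence engine -- a circle has one
  1-cycle, a sphere one 2-cavity, a torus two 1-cycles and one cavity.
  The torus is a deterministic angular grid so its diagram is exactly
  reproducible; circle and sphere samples are seeded uniform draws.

* **Pseudo-proteins** are self-avoiding C-alpha random walks with the
  canonical 3.8 Angstrom virtual-bond spacing, decorated with one side
  atom per residue (cycling C, N, O so all element pairs are populated),
  and synthetic B-factors carrying a recoverable statistical law:
  either a fixed linear combination of the protein's own topological
  feature vectors plus Gaussian noise, or an inverse-packing law
  mimicking the anti-correlation of flexibility with local crowding.
  The linear law's coefficients depend only on ``law_seed``, so an
  ensemble of proteins generated with different ``seed`` values shares
  one generating law -- exactly what across-protein blind prediction
  assumes.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .io_structures import Atom, ProteinStructure

CA_SPACING = 3.8          # consecutive C-alpha virtual bond, Angstrom
SELF_AVOID_MIN = 3.5      # min distance between non-consecutive C-alphas

LINEAR_IN_FEATURES = "linear_in_features"
INVERSE_PACKING = "inverse_packing"

_SIDE_ELEMENTS = ("C", "N", "O")
_SIDE_NAMES = {"C": "CB", "N": "ND1", "O": "OD1"}


def sample_torus(n: int = 20, major_radius: float = 3.0,
                 minor_radius: float = 1.0) -> np.ndarray:
    """Deterministic n x n angular grid on a torus of revolution."""
    if n < 10:
        raise ValueError("need n >= 10 grid steps for adequate coverage")
    if not major_radius > minor_radius > 0:
        raise ValueError("require major_radius > minor_radius > 0")
    u = np.arange(n) * 2 * np.pi / n
    v = np.arange(n) * 2 * np.pi / n
    uu, vv = np.meshgrid(u, v, indexing="ij")
    x = (major_radius + minor_radius * np.cos(vv)) * np.cos(uu)
    y = (major_radius + minor_radius * np.cos(vv)) * np.sin(uu)
    z = minor_radius * np.sin(vv)
    return np.column_stack([x.ravel(), y.ravel(), z.ravel()])


def sample_circle(n: int, radius: float = 1.0, seed: int = 0) -> np.ndarray:
    """Seeded uniform sample of a circle in the z = 0 plane."""
    if n < 20:
        warnings.warn("fewer than 20 circle points: the 1-cycle may be "
                      "poorly resolved")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            np.zeros(n)])


def sample_sphere(n: int, radius: float = 1.0, seed: int = 0) -> np.ndarray:
    """Evenly covering sample of a sphere surface, seeded.

    Uses a Fibonacci lattice (uniform point density, near-optimal
    covering radius) composed with a random rotation drawn from the
    seed, so the sample is deterministic per seed but carries no fixed
    orientation.  An evenly covering sample is what the cavity detection
    needs: i.i.d. draws leave coverage gaps whose spurious loops decay
    only slowly with n.
    """
    if n < 50:
        warnings.warn("fewer than 50 sphere points: the 2-cavity may be "
                      "poorly resolved")
    from scipy.spatial.transform import Rotation

    k = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * k + 1) / n
    theta = 2 * np.pi * k / golden
    rho = np.sqrt(1 - z * z)
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    rot = Rotation.random(
        random_state=np.random.default_rng(seed)).as_matrix()
    return radius * pts @ rot.T


@dataclass(frozen=True)
class PseudoProtein:
    """A generated structure plus the ground truth of its B-factor law."""

    structure: ProteinStructure
    bfactor_law: str
    coefficients: np.ndarray | None   # linear law weights (60,), else None
    signal: np.ndarray                # noise-free per-C-alpha signal
    noise_sigma: float


def _self_avoiding_backbone(n_residues: int, rng) -> np.ndarray:
    coords = [np.zeros(3)]
    tries_per_step = 300
    while len(coords) < n_residues:
        placed = False
        for _ in range(tries_per_step):
            step = rng.normal(size=3)
            step *= CA_SPACING / np.linalg.norm(step)
            cand = coords[-1] + step
            prior = np.array(coords[:-1]) if len(coords) > 1 else None
            if prior is None or np.min(
                    np.linalg.norm(prior - cand, axis=1)) >= SELF_AVOID_MIN:
                coords.append(cand)
                placed = True
                break
        if not placed:           # dead end: back up one residue and retry
            coords.pop()
            if not coords:
                coords = [np.zeros(3)]
    return np.array(coords)


def _build_structure(n_residues: int, seed: int) -> ProteinStructure:
    from .features import STANDARD_AA

    rng = np.random.default_rng(seed)
    backbone = _self_avoiding_backbone(n_residues, rng)
    atoms = []
    serial = 1
    for i, ca in enumerate(backbone):
        resname = STANDARD_AA[i % len(STANDARD_AA)]
        atoms.append(Atom(serial, "CA", "C", ca, 1.0, 1.0, resname, i + 1,
                          "A"))
        serial += 1
        element = _SIDE_ELEMENTS[i % len(_SIDE_ELEMENTS)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset = rng.uniform(1.5, 2.5)
        atoms.append(Atom(serial, _SIDE_NAMES[element], element,
                          ca + offset * direction, 1.0, 1.0, resname, i + 1,
                          "A"))
        serial += 1
    return ProteinStructure(f"synth{seed:04d}", tuple(atoms),
                            resolution=2.0, r_value=0.18)


def make_pseudo_protein(n_residues: int, seed: int = 0,
                        bfactor_law: str = LINEAR_IN_FEATURES,
                        noise_rel: float = 0.05,
                        law_seed: int = 0) -> PseudoProtein:
    """Generate a pseudo-protein with a recoverable B-factor law.

    ``linear_in_features``: B = 20 + w . f + eps, where f is the
    residue's 60-component topological feature vector, w is a fixed
    weight vector drawn from ``law_seed`` only, and eps is Gaussian with
    standard deviation ``noise_rel`` times the within-protein signal SD.
    ``inverse_packing``: B proportional to 1 / (1 + packing density),
    plus the same relative noise.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if bfactor_law not in (LINEAR_IN_FEATURES, INVERSE_PACKING):
        raise ValueError(f"unknown B-factor law: {bfactor_law!r}")
    structure = _build_structure(n_residues, seed)
    calphas = structure.calphas

    coefficients = None
    if bfactor_law == LINEAR_IN_FEATURES:
        from .features import topo_feature_vector
        law_rng = np.random.default_rng(law_seed)
        coefficients = law_rng.normal(size=60) / np.sqrt(60.0)
        feats = np.array([topo_feature_vector(structure, ca)
                          for ca in calphas])
        signal = 20.0 + feats @ coefficients
    else:
        from .features import packing_density
        packing = np.array([packing_density(structure, ca)
                            for ca in calphas])
        signal = 20.0 + 100.0 / (1.0 + packing)

    sd = float(signal.std())
    sigma = noise_rel * (sd if sd > 0 else 1.0)
    noise_rng = np.random.default_rng(seed + 7919)
    bfactors = signal + noise_rng.normal(scale=sigma, size=len(signal)) \
        if sigma > 0 else signal.copy()
    bfactors = np.maximum(bfactors, 0.01)

    per_residue = {ca.residue_number: b for ca, b in zip(calphas, bfactors)}
    atoms = tuple(
        dataclasses.replace(a, bfactor=per_residue[a.residue_number])
        for a in structure.atoms)
    structure = dataclasses.replace(structure, atoms=atoms)
    return PseudoProtein(structure, bfactor_law, coefficients,
                         signal, sigma)


def write_pdb(protein, path) -> None:
    """Write a structure as standard fixed-column PDB ATOM records.

    Coordinates are fixed to 3 decimals and B-factors to 2 (the format's
    precision, which defines round-trip equality); occupancy is 1.00.
    Resolution and R-value are emitted as REMARK 2 / REMARK 3 records so
    the global features survive the round trip.
    """
    structure = getattr(protein, "structure", protein)
    lines = []
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} "
                     "ANGSTROMS.")
    if structure.r_value is not None:
        lines.append("REMARK   3   R VALUE            (WORKING SET) : "
                     f"{structure.r_value:.3f}")
    for a in structure.atoms:
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain:1s}{a.residue_number:4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{a.bfactor:6.2f}          {a.element:>2s}")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
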