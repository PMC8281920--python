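"""Per-C-alpha topological, local and global features.

The atom-specific topological feature of a C-alpha, for one configuration
(element pair, kernel, diagram transform, metric, homology dimension), is
the diagram distance between the persistence diagrams of its conjugated
cloud pair.  The production feature set is 60 scalars per C-alpha: five
configuration rows

====  ===========================  ===================
row   kernel                       diagram transform
====  ===========================  ===================
1     Lorentz eta=21, nu=5         unchanged
2     exponential eta=10, kappa=1  unchanged
3     exponential eta=2,  kappa=1  diagonal reflection
4     exponential eta=2,  kappa=1  rotated 30 deg
5     exponential eta=2,  kappa=1  rotated 60 deg
====  ===========================  ===================

each crossed with metric {Bottleneck, Wasserstein} x dimension {0, 1} x
element pair {CC, CN, CO} = 12 features per row.  All clouds use the
11 Angstrom cutoff.  The feature order (row-major in the table above,
metric before dimension before pair) is frozen; models trained on the
CSV output remain portable across versions.

A second, image-like representation sweeps an exponential-kernel grid
eta in {1, 2, 3, 4, 5, 10, 15, 20} (rows) by kappa in {1..10} (columns)
for each element pair (channels), giving an (8, 10, 3) tensor per
C-alpha.  The scalar placed in each cell is a conjugated-diagram distance
under that kernel; which metric/dimension is used is configurable, with
dimension-0 Wasserstein (p=1) as the default.

Auxiliary features: packing density (heavy-atom count within the cutoff),
amino-acid type and secondary structure as one-hots, occupancy, and the
protein-level R-value, resolution and heavy-atom count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diagram_metrics as dm
from .conjugation import (CC, CN, CO, ELEMENT_PAIRS, PAIR_UNION,
                          ConjugationConfig, conjugate)
from .filtration import (EXPONENTIAL, LORENTZ, KernelSpec,
                         kernel_matrix_from_distances)
from .io_structures import COIL, SS_CLASSES, Atom, ProteinStructure
from .persistence import PersistenceDiagram, rips_persistence

BOTTLENECK = "bottleneck"
WASSERSTEIN = "wasserstein"
METRICS = (BOTTLENECK, WASSERSTEIN)
DIMS = (0, 1)

IMAGE_ETAS = (1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 15.0, 20.0)
IMAGE_KAPPAS = tuple(float(k) for k in range(1, 11))
IMAGE_SHAPE = (len(IMAGE_ETAS), len(IMAGE_KAPPAS), len(ELEMENT_PAIRS))

STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass(frozen=True)
class FeatureRow:
    """One configuration row: a kernel and a diagram transform."""

    kernel: KernelSpec
    transform: str
    label: str


#: The five production configuration rows (12 features each).
DEFAULT_FEATURE_ROWS = (
    FeatureRow(KernelSpec(LORENTZ, 21.0, 5.0), dm.IDENTITY, "lor21v5"),
    FeatureRow(KernelSpec(EXPONENTIAL, 10.0, 1.0), dm.IDENTITY, "exp10k1"),
    FeatureRow(KernelSpec(EXPONENTIAL, 2.0, 1.0), dm.REFLECT_DIAGONAL,
               "exp2k1refl"),
    FeatureRow(KernelSpec(EXPONENTIAL, 2.0, 1.0), dm.ROTATE30, "exp2k1rot30"),
    FeatureRow(KernelSpec(EXPONENTIAL, 2.0, 1.0), dm.ROTATE60, "exp2k1rot60"),
)


@dataclass(frozen=True)
class FeatureConfig:
    """Topological feature generation settings."""

    rows: tuple = DEFAULT_FEATURE_ROWS
    cutoff: float = 11.0
    pair_mode: str = PAIR_UNION
    wasserstein_p: float = 1.0


def feature_names(config: FeatureConfig | None = None) -> list:
    config = config or FeatureConfig()
    names = []
    for row in config.rows:
        for metric in ("B", "W"):
            for dim in DIMS:
                for pair in ELEMENT_PAIRS:
                    names.append(f"{row.label}_{metric}{dim}_{pair}")
    return names


def _empty_diagrams(max_dim: int, cap: float) -> list:
    return [PersistenceDiagram(d, np.empty((0, 2)), cap)
            for d in range(max_dim + 1)]


def conjugated_diagrams(structure, calpha, pair, kernel, *,
                        cutoff: float = 11.0, pair_mode: str = PAIR_UNION,
                        max_dim: int = 1):
    """Kernel-filtration persistence diagrams of the conjugated pair.

    Returns (full-cloud diagrams, reduced-cloud diagrams), lists indexed
    by dimension.  An empty reduced cloud yields empty diagrams.
    """
    cfg = ConjugationConfig(cutoff=cutoff, pair_mode=pair_mode)
    pair_clouds = conjugate(structure, calpha, pair, cfg)
    full = rips_persistence(
        _kernel_matrix(pair_clouds.full_cloud, kernel), max_dim=max_dim)
    if len(pair_clouds.reduced_cloud) == 0:
        reduced = _empty_diagrams(max_dim, 1.0)
    else:
        reduced = rips_persistence(
            _kernel_matrix(pair_clouds.reduced_cloud, kernel),
            max_dim=max_dim)
    return full, reduced


def _kernel_matrix(points, kernel):
    from .filtration import kernel_filtration_matrix
    return kernel_filtration_matrix(points, kernel)


def _diagram_distance(dgm_a, dgm_b, transform, metric, p=1.0) -> float:
    a = dm.transform_diagram(dgm_a, transform)
    b = dm.transform_diagram(dgm_b, transform)
    if metric == BOTTLENECK:
        return dm.bottleneck(a, b)
    if metric == WASSERSTEIN:
        return dm.wasserstein(a, b, p=p)
    raise ValueError(f"unknown metric: {metric!r}")


def asph_distance_feature(structure, calpha, pair, kernel, *,
                          transform: str = dm.IDENTITY,
                          metric: str = WASSERSTEIN, dim: int = 0,
                          cutoff: float = 11.0,
                          pair_mode: str = PAIR_UNION,
                          wasserstein_p: float = 1.0) -> float:
    """One atom-specific topological feature: a conjugated-diagram distance."""
    full, reduced = conjugated_diagrams(
        structure, calpha, pair, kernel,
        cutoff=cutoff, pair_mode=pair_mode, max_dim=dim)
    return _diagram_distance(full[dim], reduced[dim], transform, metric,
                             p=wasserstein_p)


def topo_feature_vector(structure, calpha,
                        config: FeatureConfig | None = None) -> np.ndarray:
    """The full topological feature vector of one C-alpha (60 scalars).

    Conjugated diagrams are computed once per distinct (kernel, element
    pair) combination and shared across transforms, metrics and
    dimensions.
    """
    config = config or FeatureConfig()
    max_dim = max(DIMS)
    cache = {}
    for row in config.rows:
        for pair in ELEMENT_PAIRS:
            key = (row.kernel, pair)
            if key not in cache:
                cache[key] = conjugated_diagrams(
                    structure, calpha, pair, row.kernel,
                    cutoff=config.cutoff, pair_mode=config.pair_mode,
                    max_dim=max_dim)
    values = []
    for row in config.rows:
        for metric in METRICS:
            for dim in DIMS:
                for pair in ELEMENT_PAIRS:
                    full, reduced = cache[(row.kernel, pair)]
                    values.append(_diagram_distance(
                        full[dim], reduced[dim], row.transform, metric,
                        p=config.wasserstein_p))
    return np.array(values)


def ph_image(structure, calpha, *, metric: str = WASSERSTEIN, dim: int = 0,
             cutoff: float = 11.0, pair_mode: str = PAIR_UNION,
             wasserstein_p: float = 1.0) -> np.ndarray:
    """The (8, 10, 3) multiscale image tensor of one C-alpha.

    Rows sweep the exponential kernel length scale eta, columns the power
    kappa, channels the element pairs CC/CN/CO.  Pairwise distances of
    each cloud are computed once and re-kernelised per cell.
    """
    from scipy.spatial.distance import pdist, squareform

    cfg = ConjugationConfig(cutoff=cutoff, pair_mode=pair_mode)
    image = np.zeros(IMAGE_SHAPE)
    for channel, pair in enumerate(ELEMENT_PAIRS):
        clouds = conjugate(structure, calpha, pair, cfg)
        dist_full = (squareform(pdist(clouds.full_cloud))
                     if len(clouds.full_cloud) > 1 else np.zeros((1, 1)))
        dist_red = (squareform(pdist(clouds.reduced_cloud))
                    if len(clouds.reduced_cloud) > 1 else None)
        for i, eta in enumerate(IMAGE_ETAS):
            for j, kappa in enumerate(IMAGE_KAPPAS):
                spec = KernelSpec(EXPONENTIAL, eta, kappa)
                full = rips_persistence(
                    kernel_matrix_from_distances(dist_full, spec),
                    max_dim=dim)
                if len(clouds.reduced_cloud) == 0:
                    reduced = _empty_diagrams(dim, 1.0)
                elif dist_red is None:
                    reduced = rips_persistence(np.zeros((1, 1)),
                                               max_dim=dim, cap=1.0)
                else:
                    reduced = rips_persistence(
                        kernel_matrix_from_distances(dist_red, spec),
                        max_dim=dim)
                image[i, j, channel] = _diagram_distance(
                    full[dim], reduced[dim], dm.IDENTITY, metric,
                    p=wasserstein_p)
    return image


def packing_density(structure: ProteinStructure, calpha: Atom,
                    cutoff: float = 11.0) -> int:
    """Number of heavy atoms strictly within the cutoff, excluding the centre."""
    count = 0
    for atom in structure.atoms:
        if atom.serial == calpha.serial:
            continue
        if np.linalg.norm(atom.coords - calpha.coords) < cutoff:
            count += 1
    return count


def local_feature_names() -> list:
    names = ["packing_density", "occupancy"]
    names += [f"aa_{aa}" for aa in STANDARD_AA] + ["aa_OTHER"]
    names += [f"ss_{ss}" for ss in SS_CLASSES]
    return names


GLOBAL_FEATURE_NAMES = ["r_value", "resolution", "n_heavy_atoms"]


def _aa_onehot(residue_name: str) -> np.ndarray:
    vec = np.zeros(len(STANDARD_AA) + 1)
    try:
        vec[STANDARD_AA.index(residue_name)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _ss_onehot(ss_class: str) -> np.ndarray:
    vec = np.zeros(len(SS_CLASSES))
    vec[SS_CLASSES.index(ss_class)] = 1.0
    return vec


def assemble_feature_table(structures, stride_tables=None,
                           config: FeatureConfig | None = None,
                           show_progress: bool = False) -> pd.DataFrame:
    """One row per C-alpha: topological + local + global features + B-factor.

    ``stride_tables`` maps pdb_id -> SecondaryStructureTable; a residue
    with no annotation is classed as coil (with a warning when a table
    was supplied for its protein).  Proteins must carry resolution and
    R-value headers so no feature column has missing values.
    """
    config = config or FeatureConfig()
    stride_tables = stride_tables or {}
    topo_names = feature_names(config)
    rows = []
    for structure in sorted(structures, key=lambda s: s.pdb_id):
        if structure.resolution is None or structure.r_value is None:
            raise ValueError(
                f"{structure.pdb_id}: resolution and R-value are required "
                "global features; supply them in the PDB header")
        ss_table = stride_tables.get(structure.pdb_id)
        calphas = sorted(structure.calphas,
                         key=lambda a: (a.chain, a.residue_number))
        for calpha in calphas:
            topo = topo_feature_vector(structure, calpha, config)
            if ss_table is not None:
                key = (calpha.chain, calpha.residue_number)
                if key in ss_table.assignments:
                    ss = ss_table.assignments[key]
                else:
                    warnings.warn(
                        f"{structure.pdb_id} {key}: no secondary-structure "
                        "annotation, classing as coil")
                    ss = COIL
            else:
                ss = COIL
            record = {
                "pdb_id": structure.pdb_id,
                "chain": calpha.chain,
                "residue_number": calpha.residue_number,
                **dict(zip(topo_names, topo)),
                "packing_density": packing_density(structure, calpha,
                                                   config.cutoff),
                "occupancy": calpha.occupancy,
                **dict(zip([f"aa_{aa}" for aa in STANDARD_AA] + ["aa_OTHER"],
                           _aa_onehot(calpha.residue_name))),
                **dict(zip([f"ss_{s}" for s in SS_CLASSES], _ss_onehot(ss))),
                "r_value": structure.r_value,
                "resolution": structure.resolution,
                "n_heavy_atoms": structure.n_heavy_atoms,
                "bfactor": calpha.bfactor,
            }
            rows.append(record)
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["pdb_id", "chain", "residue_number"]).reset_index(drop=True)


def all_feature_columns(config: FeatureConfig | None = None) -> list:
    """Every model-input column of an assembled feature table, in order."""
    return feature_names(config) + local_feature_names() + GLOBAL_FEATURE_NAMES
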