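"""Reading protein structures and secondary-structure annotations.

PDB coordinate parsing is delegated to Biopython's ``Bio.PDB``; this
module normalises the result into a flat, immutable list of heavy atoms:

* only model 1 of multi-model files is used;
* HETATM records (ligands, waters) and hydrogens are excluded;
* alternate locations are resolved to the highest-occupancy conformer,
  first listed on a tie;
* all chains are pooled into one atom set, ordered by serial number.

Header resolution (REMARK 2) is taken from Biopython's header parse; the
crystallographic R-value is scanned from REMARK 3 lines directly, since
no installed parser exposes it for PDB-format headers.  Both are optional
(``None`` when absent).

Secondary structure is consumed from STRIDE ASG output files; it is an
auxiliary feature source, never computed here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

HELIX, STRAND, TURN, COIL = "helix", "strand", "turn", "coil"
SS_CLASSES = (HELIX, STRAND, TURN, COIL)

# STRIDE one-letter codes; anything else maps to coil.
_STRIDE_MAP = {
    "H": HELIX, "G": HELIX, "I": HELIX,
    "E": STRAND, "B": STRAND, "b": STRAND,
    "T": TURN,
}

_HYDROGEN = {"H", "D"}


class PDBParseError(ValueError):
    """Structured parse failure; carries the offending line number if known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a protein structure (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    bfactor: float
    occupancy: float
    residue_name: str
    residue_number: int
    chain: str

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.bfactor < 0:
            raise ValueError(f"negative B-factor {self.bfactor}")

    @property
    def is_calpha(self) -> bool:
        return self.name == "CA" and self.element == "C"


@dataclass(frozen=True)
class ProteinStructure:
    """Heavy atoms of model 1, plus optional header metadata."""

    pdb_id: str
    atoms: tuple
    resolution: float | None = None
    r_value: float | None = None

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.element not in _HYDROGEN)

    @property
    def calphas(self) -> tuple:
        return tuple(a for a in self.atoms if a.is_calpha)

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class SecondaryStructureTable:
    """Mapping (chain, residue_number) -> secondary-structure class."""

    assignments: dict = field(default_factory=dict)

    def get(self, chain: str, residue_number: int, default: str = COIL) -> str:
        return self.assignments.get((chain, residue_number), default)

    def __len__(self) -> int:
        return len(self.assignments)

    def check_against(self, structure: ProteinStructure) -> list:
        """Warn about annotated residues absent from the structure."""
        present = {(a.chain, a.residue_number) for a in structure.atoms}
        extra = [key for key in self.assignments if key not in present]
        if extra:
            warnings.warn(
                f"{len(extra)} secondary-structure entries refer to residues "
                f"not present in {structure.pdb_id}")
        return extra


def _element_of(bio_atom) -> str:
    elem = (bio_atom.element or "").strip().upper()
    if not elem:
        # older PDB dialects: infer from the atom name (first letter that
        # is not a digit; two-letter elements are rare in proteins)
        name = bio_atom.get_name().strip()
        elem = next((ch for ch in name if ch.isalpha()), "").upper()
    return elem


def _pick_altloc(bio_atom):
    """Highest-occupancy conformer, first listed on a tie."""
    if not bio_atom.is_disordered():
        return bio_atom
    children = bio_atom.disordered_get_list()
    best = children[0]
    for child in children[1:]:
        if (child.get_occupancy() or 0.0) > (best.get_occupancy() or 0.0):
            best = child
    return best


def read_pdb(path) -> ProteinStructure:
    """Parse a PDB file into a normalised ``ProteinStructure``.

    Raises :class:`PDBParseError` on a missing file, a file with no ATOM
    records, or an unparseable coordinate field.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    pdb_id = _stem(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(pdb_id, path)
    except FileNotFoundError:
        raise PDBParseError(f"no such file: {path}")
    except PDBConstructionException as exc:
        raise PDBParseError(str(exc), line=_line_of(exc)) from exc

    models = list(structure.get_models())
    if not models:
        raise PDBParseError(f"{path}: no ATOM records")
    model = models[0]

    atoms = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _ = residue.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            for bio_atom in residue:
                chosen = _pick_altloc(bio_atom)
                element = _element_of(chosen)
                if element in _HYDROGEN:
                    continue
                atoms.append(Atom(
                    serial=int(chosen.get_serial_number()),
                    name=bio_atom.get_name().strip(),
                    element=element,
                    coords=np.asarray(chosen.get_coord(), dtype=float),
                    bfactor=float(chosen.get_bfactor() or 0.0),
                    occupancy=float(
                        min(max(chosen.get_occupancy() or 1.0, 0.0), 1.0)),
                    residue_name=residue.get_resname().strip(),
                    residue_number=int(resseq),
                    chain=chain.get_id(),
                ))
    if not atoms:
        raise PDBParseError(f"{path}: no ATOM records")
    atoms.sort(key=lambda a: a.serial)

    header = parser.get_header() or {}
    resolution = header.get("resolution")
    resolution = float(resolution) if resolution is not None else None
    r_value = _scan_r_value(path)
    return ProteinStructure(pdb_id, tuple(atoms), resolution, r_value)


def validate_bfactors(structure: ProteinStructure) -> list:
    """Residues whose C-alpha B-factor is exactly zero.

    A zero temperature factor is unphysical; the caller decides whether to
    drop the protein (the conservative dataset-level rule) or just the
    flagged residues.
    """
    return [(a.chain, a.residue_number)
            for a in structure.calphas if a.bfactor == 0.0]


def read_stride(path) -> SecondaryStructureTable:
    """Parse STRIDE ASG records into a secondary-structure table.

    The one-letter code column decides the class: H/G/I -> helix, E/B ->
    strand, T -> turn, everything else -> coil.
    """
    table = SecondaryStructureTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ASG"):
                continue
            fields = line.split()
            # ASG  resname chain resnum ordinal code fullname phi psi area
            if len(fields) < 6:
                raise PDBParseError("malformed STRIDE ASG record",
                                    line=lineno)
            chain = fields[2]
            try:
                resnum = int(fields[3])
            except ValueError as exc:
                raise PDBParseError(
                    f"bad residue number in STRIDE record: {fields[3]!r}",
                    line=lineno) from exc
            code = fields[5]
            table.assignments[(chain, resnum)] = _STRIDE_MAP.get(code, COIL)
    return table


def _scan_r_value(path) -> float | None:
    pattern = re.compile(
        r"^REMARK\s+3\s+R VALUE\s*(?:\(WORKING SET\))?\s*:\s*([0-9.]+)")
    try:
        with open(path) as fh:
            for line in fh:
                match = pattern.match(line)
                if match:
                    return float(match.group(1))
                if line.startswith("ATOM"):
                    break
    except (OSError, UnicodeDecodeError):
        return None
    return None


def _line_of(exc) -> int | None:
    match = re.search(r"line (\d+)", str(exc))
    return int(match.group(1)) if match else None


def _stem(path) -> str:
    import os
    base = os.path.basename(str(path))
    return base.rsplit(".", 1)[0] if "." in base else base
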