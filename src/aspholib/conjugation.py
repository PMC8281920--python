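"""Element-specific subsets and conjugated point-cloud pairs.

The atom-specific construction works on a pair of clouds around a centre
atom (here a C-alpha): the *full* cloud contains every atom of an
element-specific subset strictly within the cutoff radius of the centre
(the centre itself included, at distance zero), and the *reduced* cloud
is the identical set minus the centre.  The persistence-diagram distance
between the two is the centre atom's topological signature.

Element-specific pairs restrict the subset by chemistry: CC (carbons
only), CN (carbons and nitrogens), CO (carbons and oxygens).  Sulfur and
other heavy elements never enter a cloud.  Two subset conventions are
offered:

* ``pair_union`` (default): all atoms whose element is either member of
  the pair;
* ``center_plus_partner``: only the partner element's atoms, with the
  centre C-alpha added separately.

Both are element-set readings of the same construction; the default is
the literal union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_structures import Atom, ProteinStructure

CC, CN, CO = "CC", "CN", "CO"
ELEMENT_PAIRS = (CC, CN, CO)

PAIR_UNION = "pair_union"
CENTER_PLUS_PARTNER = "center_plus_partner"

_PAIR_ELEMENTS = {CC: {"C"}, CN: {"C", "N"}, CO: {"C", "O"}}
_PARTNER = {CC: "C", CN: "N", CO: "O"}


@dataclass(frozen=True)
class ConjugationConfig:
    """Cutoff radius r_c (Angstrom) and subset convention."""

    cutoff: float = 11.0
    pair_mode: str = PAIR_UNION

    def __post_init__(self):
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if self.pair_mode not in (PAIR_UNION, CENTER_PLUS_PARTNER):
            raise ValueError(f"unknown pair_mode: {self.pair_mode!r}")


@dataclass(frozen=True)
class ConjugatedPair:
    """The (full, reduced) cloud pair around one centre atom.

    ``full_cloud`` is an (n, 3) coordinate array containing the centre;
    ``reduced_cloud`` is the same array with the centre's row removed, so
    ``len(full_cloud) == len(reduced_cloud) + 1`` always.
    """

    center: Atom
    full_cloud: np.ndarray
    reduced_cloud: np.ndarray
    pair: str

    def __post_init__(self):
        object.__setattr__(self, "full_cloud",
                           np.asarray(self.full_cloud, dtype=float))
        object.__setattr__(self, "reduced_cloud",
                           np.asarray(self.reduced_cloud, dtype=float))


def element_subset(structure: ProteinStructure, pair: str,
                   mode: str = PAIR_UNION) -> list:
    """Atoms of the element-specific subset, ordered by serial number."""
    if pair not in ELEMENT_PAIRS:
        raise ValueError(f"unknown element pair: {pair!r}")
    if mode == PAIR_UNION:
        allowed = _PAIR_ELEMENTS[pair]
    elif mode == CENTER_PLUS_PARTNER:
        allowed = {_PARTNER[pair]}
    else:
        raise ValueError(f"unknown pair_mode: {mode!r}")
    subset = [a for a in structure.atoms if a.element in allowed]
    subset.sort(key=lambda a: a.serial)
    return subset


def conjugate(structure: ProteinStructure, calpha: Atom, pair: str,
              config: ConjugationConfig | None = None) -> ConjugatedPair:
    """Build the conjugated cloud pair around a C-alpha.

    The full cloud is every subset atom strictly within ``config.cutoff``
    of the centre; the centre is always a member (distance 0).  The
    reduced cloud drops the centre atom itself -- not atoms that merely
    share its coordinates.
    """
    if not calpha.is_calpha:
        raise ValueError(
            f"centre atom {calpha.serial} ({calpha.name}) is not a C-alpha")
    config = config or ConjugationConfig()
    subset = element_subset(structure, pair, config.pair_mode)

    center_xyz = calpha.coords
    if not any(a.serial == calpha.serial for a in subset):
        # centre not in the subset (center_plus_partner mode): prepend it
        subset = [calpha] + subset
    full, reduced = [], []
    for atom in subset:
        if atom.serial == calpha.serial:
            full.append(atom.coords)  # the centre, at distance 0
        elif np.linalg.norm(atom.coords - center_xyz) < config.cutoff:
            full.append(atom.coords)
            reduced.append(atom.coords)
    full_cloud = np.array(full, dtype=float)
    reduced_cloud = (np.array(reduced, dtype=float)
                     if reduced else np.empty((0, 3)))
    return ConjugatedPair(calpha, full_cloud, reduced_cloud, pair)
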