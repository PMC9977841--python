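"""Molecular structures, atom-mapped reactions, and bond-change categories.

A reaction is an atom-mapped triple (reactant, optional reference transition
state, product): atom i of the reactant is atom i of the product, so
coordinate-wise interpolation and per-pair comparisons are well defined.
Coordinates are stored in Angstrom; distance errors are conventionally
reported in pm (100 pm = 1 A).
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

PM_PER_ANGSTROM = 100.0
#: default covalent-bond criterion for bond-change classification, pm
DEFAULT_BOND_THRESHOLD_PM = 156.6

_SYMBOLS = {
    1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 15: "P", 16: "S", 17: "Cl",
    35: "Br", 53: "I",
}
_NUMBERS = {v: k for k, v in _SYMBOLS.items()}

#: atomic masses (amu) for the supported elements
ATOMIC_MASSES = {
    1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999, 9: 18.998, 15: 30.974,
    16: 32.06, 17: 35.45, 35: 79.904, 53: 126.904,
}


def symbol_for(z: int) -> str:
    try:
        return _SYMBOLS[int(z)]
    except KeyError:
        raise ValueError(f"unsupported atomic number {z}") from None


def number_for(symbol: str) -> int:
    try:
        return _NUMBERS[symbol.strip().capitalize() if len(symbol) > 1 else symbol.strip().upper()]
    except KeyError:
        raise ValueError(f"unsupported element symbol {symbol!r}") from None


@dataclasses.dataclass(eq=False)
class Structure:
    """One molecular conformation: atomic numbers plus Cartesian coordinates (A)."""

    atomic_numbers: np.ndarray
    coordinates: np.ndarray
    label: Optional[str] = None  # reactant | product | interpolated | ts

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.atomic_numbers.ndim != 1 or self.atomic_numbers.size < 1:
            raise ValueError("atomic_numbers must be a non-empty 1-D sequence")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")
        if self.coordinates.shape != (self.atomic_numbers.size, 3):
            raise ValueError(
                f"coordinates must have shape ({self.atomic_numbers.size}, 3), "
                f"got {self.coordinates.shape}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.atomic_numbers.size

    def distance_matrix(self) -> np.ndarray:
        """Symmetric hollow matrix of pairwise distances, A."""
        if self.n_atoms == 1:
            return np.zeros((1, 1))
        return squareform(pdist(self.coordinates))

    def strict_pair_distances(self, pair_index: np.ndarray) -> np.ndarray:
        """Distances (A) for the given (i, j) pair rows."""
        d = self.coordinates[pair_index[:, 0]] - self.coordinates[pair_index[:, 1]]
        return np.linalg.norm(d, axis=1)

    def copy(self, label: Optional[str] = None) -> "Structure":
        return Structure(
            self.atomic_numbers.copy(), self.coordinates.copy(),
            label if label is not None else self.label,
        )


def strict_pairs(n_atoms: int) -> np.ndarray:
    """All unordered pairs (i, j) with i > j, row-major in i."""
    idx = [(i, j) for i in range(n_atoms) for j in range(i)]
    return np.asarray(idx, dtype=np.int64).reshape(-1, 2)


def all_pairs(n_atoms: int) -> np.ndarray:
    """All pairs (i, j) with i >= j (diagonal included), N(N+1)/2 rows."""
    idx = [(i, j) for i in range(n_atoms) for j in range(i + 1)]
    return np.asarray(idx, dtype=np.int64).reshape(-1, 2)


@dataclasses.dataclass(eq=False)
class Reaction:
    """Atom-mapped reactant/product pair with optional reference TS and labels.

    ``properties`` maps a structure role ("reactant"/"product"/"ts") to a dict
    with any of the keys "E" (kcal/mol), "S_vib", "S_rot".
    """

    reactant: Structure
    product: Structure
    ts_ref: Optional[Structure] = None
    properties: Optional[dict] = None
    reaction_id: str = ""

    def __post_init__(self):
        frames = [self.reactant, self.product] + (
            [self.ts_ref] if self.ts_ref is not None else []
        )
        n = frames[0].n_atoms
        for f in frames[1:]:
            if f.n_atoms != n:
                raise ValueError("all frames of a reaction must share N_atom")
            if not np.array_equal(f.atomic_numbers, frames[0].atomic_numbers):
                raise ValueError(
                    "atom mapping is positional: element sequences must be "
                    "identical across frames"
                )

    @property
    def n_atoms(self) -> int:
        return self.reactant.n_atoms

    def reverse(self) -> "Reaction":
        """Swap reactant and product; the TS (if any) is unchanged."""
        props = None
        if self.properties is not None:
            props = dict(self.properties)
            r, p = props.get("reactant"), props.get("product")
            if r is not None:
                props["product"] = r
            else:
                props.pop("product", None)
            if p is not None:
                props["reactant"] = p
            else:
                props.pop("reactant", None)
        return Reaction(
            reactant=self.product.copy(label="reactant"),
            product=self.reactant.copy(label="product"),
            ts_ref=self.ts_ref.copy() if self.ts_ref is not None else None,
            properties=props,
            reaction_id=self.reaction_id,
        )


class BondChange(enum.Enum):
    """Bond-change category of an atom pair across a reaction."""

    NONE_NONE = "none_none"    # unbonded in both reactant and product
    FORMATION = "formation"    # unbonded in reactant, bonded in product
    BREAKAGE = "breakage"      # bonded in reactant, unbonded in product
    BOND_BOND = "bond_bond"    # bonded in both


def kabsch_align(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper-rotation + translation superposition of point sets.

    Returns the transformed mobile coordinates and the resulting RMSD (A).
    Reflections are excluded, so chirality is preserved.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    m0, t0 = mobile - cm, target - ct
    if np.allclose(m0, 0) and np.allclose(t0, 0):
        # coincident point sets: pure translation
        out = mobile - cm + ct
        return out, float(np.sqrt(np.mean(np.sum((out - target) ** 2, axis=1))))
    rot, _ = Rotation.align_vectors(t0, m0)
    out = m0 @ rot.as_matrix().T + ct
    rmsd = float(np.sqrt(np.mean(np.sum((out - target) ** 2, axis=1))))
    return out, rmsd


def interpolate(reaction: Reaction, fraction: float = 0.5, align: bool = False) -> Structure:
    """Coordinate-wise convex combination of reactant and product.

    With ``align=True`` the product is first rigidly superposed onto the
    reactant (Kabsch, no reflection) so that arbitrary input poses do not
    produce collapsed interpolations; data that is already consistently
    posed should use ``align=False``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"interpolation fraction must be in [0, 1], got {fraction}")
    xp = reaction.product.coordinates
    if align:
        xp, _ = kabsch_align(xp, reaction.reactant.coordinates)
    coords = (1.0 - fraction) * reaction.reactant.coordinates + fraction * xp
    return Structure(reaction.reactant.atomic_numbers.copy(), coords, label="interpolated")


def classify_pairs(
    reaction: Reaction, theta_bond_pm: float = DEFAULT_BOND_THRESHOLD_PM
) -> list[BondChange]:
    """Classify every strict pair (i > j) by bond change across the reaction.

    A pair is "bonded" in a structure when its interatomic distance is below
    ``theta_bond_pm`` (default 156.6 pm).
    """
    pairs = strict_pairs(reaction.n_atoms)
    theta_a = theta_bond_pm / PM_PER_ANGSTROM
    d_r = reaction.reactant.strict_pair_distances(pairs)
    d_p = reaction.product.strict_pair_distances(pairs)
    out = []
    for br, bp in zip(d_r < theta_a, d_p < theta_a):
        if br and bp:
            out.append(BondChange.BOND_BOND)
        elif br:
            out.append(BondChange.BREAKAGE)
        elif bp:
            out.append(BondChange.FORMATION)
        else:
            out.append(BondChange.NONE_NONE)
    return out
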