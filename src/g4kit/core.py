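"""Core domain types: atoms, models, structures, trajectories, selections.

Coordinates are stored in Angstrom throughout; quantities that the wider
literature reports in nm (channel radius of gyration, solvent-accessible
surface areas) are converted only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Model",
    "Structure",
    "Trajectory",
    "AtomSelector",
    "select",
]

#: residues recognised as standard deoxyribonucleotides
NUCLEIC_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U"}

ONE_LETTER = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U",
              "A": "A", "C": "C", "G": "G", "T": "T", "U": "U"}


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of one conformation.

    ``name`` follows wwPDB conventions with primed sugar atoms ("C1'",
    "O4'", "O3'"); ``xyz`` is in Angstrom.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    xyz: np.ndarray

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise ValueError(f"atom {self.name}: xyz must be a finite 3-vector")
        object.__setattr__(self, "xyz", xyz)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.name)


class Model:
    """One conformation: an ordered list of atoms with a coordinate array."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms = list(atoms)
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom {dup} in model")
        self._coords = np.array([a.xyz for a in self.atoms], dtype=float) \
            if self.atoms else np.empty((0, 3))

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return self._coords

    def roster(self) -> list[tuple[str, int, str]]:
        return [a.key for a in self.atoms]

    def with_coords(self, coords: np.ndarray) -> "Model":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self._coords.shape:
            raise ValueError("coordinate array shape mismatch")
        return Model([
            AtomRecord(a.serial, a.name, a.element, a.residue_name,
                       a.residue_index, a.chain_id, c)
            for a, c in zip(self.atoms, coords)
        ])

    def atom(self, chain_id: str, residue_index: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.key == (chain_id, residue_index, name):
                return a
        raise KeyError(f"no atom {(chain_id, residue_index, name)}")

    def __len__(self) -> int:
        return len(self.atoms)


class Structure:
    """A molecule with one or more conformations sharing one atom roster."""

    def __init__(self, models: Sequence[Model]):
        if not models:
            raise ValueError("Structure needs at least one model")
        if len(models[0]) == 0:
            raise ValueError("Structure models must contain atoms")
        roster0 = models[0].roster()
        for i, m in enumerate(models[1:], start=2):
            r = m.roster()
            if r != roster0:
                missing = set(roster0) ^ set(r)
                raise ValueError(
                    f"model {i} roster differs from model 1; mismatched atoms: "
                    f"{sorted(missing)[:5]}")
        self.models = list(models)
        self._residues: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(models[0].atoms):
            self._residues.setdefault((a.chain_id, a.residue_index), []).append(i)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def residue_table(self) -> dict[tuple[str, int], list[int]]:
        """(chain_id, residue_index) -> atom indices (roster order)."""
        return self._residues

    @property
    def residue_names(self) -> dict[tuple[str, int], str]:
        m = self.models[0]
        return {key: m.atoms[idx[0]].residue_name
                for key, idx in self._residues.items()}

    @property
    def sequence(self) -> str:
        """5'->3' base string, chain-major residue order; X for non-nucleic."""
        names = self.residue_names
        return "".join(ONE_LETTER.get(names[k], "X") for k in self.residue_keys)

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return sorted(self._residues, key=lambda k: (k[0], k[1]))

    def guanine_residues(self) -> list[tuple[str, int]]:
        names = self.residue_names
        return [k for k in self.residue_keys if names[k] in ("DG", "G")]


class Trajectory:
    """A Structure whose models are frames on a uniform time grid (ns)."""

    def __init__(self, structure: Structure, times: Sequence[float]):
        times = np.asarray(times, dtype=float)
        if len(times) != structure.n_models:
            raise ValueError("times length must equal number of models")
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValueError("times must be uniformly spaced")
        self.structure = structure
        self.times = times

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class AtomSelector:
    """Select atoms by residue index and (optionally) atom name.

    Empty ``atom_names`` means all atoms of the listed residues; empty
    ``residue_indices`` means all residues.
    """

    residue_indices: set[int] = field(default_factory=set)
    atom_names: set[str] = field(default_factory=set)
    chain_ids: set[str] = field(default_factory=set)

    def matches(self, atom: AtomRecord) -> bool:
        if self.residue_indices and atom.residue_index not in self.residue_indices:
            return False
        if self.atom_names and atom.name not in self.atom_names:
            return False
        if self.chain_ids and atom.chain_id not in self.chain_ids:
            return False
        return True


def select(structure: Structure, selector: AtomSelector) -> list[int]:
    """Atom indices (roster order) matched by ``selector``; may be empty."""
    model = structure.models[0]
    return [i for i, a in enumerate(model.atoms) if selector.matches(a)]


def heavy_atom_indices(model: Model) -> list[int]:
    return [i for i, a in enumerate(model.atoms) if a.element != "H"]
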