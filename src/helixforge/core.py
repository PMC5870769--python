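"""Hierarchical structure model: Assembly > Polymer > Residue > Atom.

Coordinates are stored in ångströms as float64.  The hierarchy is
navigable in both directions: every atom knows its residue, every
residue its chain, every chain its assembly.  Rigid-body manipulation
(rotation about an arbitrary axis, translation) acts on whole polymers
or assemblies and never changes topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Polymer",
    "Assembly",
    "Primitive",
    "primitive_of",
    "rotate",
    "translate",
    "relabel",
    "rotation_matrix",
]

#: Alphabet used when relabelling chains (62 single-character ids).
CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ" "abcdefghijklmnopqrstuvwxyz" "0123456789"
)

PROTEIN_BACKBONE = ("N", "CA", "C", "O")


class Atom:
    """A single atom: a label, an element, a 3-vector of coordinates in Å."""

    __slots__ = ("label", "element", "_coords", "serial", "parent")

    def __init__(self, label: str, coords, element: str | None = None,
                 serial: int = 1):
        if not label:
            raise ValueError("atom label must be non-empty")
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {label!r}: coords must be a finite 3-vector")
        self.label = label
        self.element = element if element is not None else label.strip()[0]
        self._coords = coords
        self.serial = int(serial)
        self.parent: "Residue | None" = None

    @property
    def coords(self) -> np.ndarray:
        return self._coords

    @coords.setter
    def coords(self, value) -> None:
        value = np.asarray(value, dtype=float)
        if value.shape != (3,) or not np.all(np.isfinite(value)):
            raise ValueError("coords must be a finite 3-vector")
        self._coords = value

    def __repr__(self) -> str:  # pragma: no cover
        x, y, z = self._coords
        return f"<Atom {self.label} ({x:.3f}, {y:.3f}, {z:.3f})>"


class Residue:
    """An ordered collection of uniquely labelled atoms plus metadata."""

    __slots__ = ("mol_code", "insertion_id", "atoms", "tags", "parent")

    def __init__(self, mol_code: str, insertion_id: str = "1",
                 atoms: Iterable[Atom] = ()):
        self.mol_code = mol_code
        self.insertion_id = str(insertion_id)
        self.atoms: dict[str, Atom] = {}
        self.tags: dict = {}
        self.parent: "Polymer | None" = None
        for atom in atoms:
            self.add_atom(atom)

    def add_atom(self, atom: Atom) -> None:
        if atom.label in self.atoms:
            raise ValueError(
                f"duplicate atom label {atom.label!r} in residue "
                f"{self.mol_code} {self.insertion_id}")
        atom.parent = self
        self.atoms[atom.label] = atom

    def __getitem__(self, label: str) -> Atom:
        return self.atoms[label]

    def __contains__(self, label: str) -> bool:
        return label in self.atoms

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms.values())

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def is_backbone_complete(self) -> bool:
        """True when the residue holds all of N, CA, C, O."""
        return all(lbl in self.atoms for lbl in PROTEIN_BACKBONE)

    def backbone_atoms(self) -> list[Atom]:
        missing = [lbl for lbl in PROTEIN_BACKBONE if lbl not in self.atoms]
        if missing:
            raise ValueError(
                f"residue {self.mol_code} {self.insertion_id} is missing "
                f"backbone atom(s) {missing}")
        return [self.atoms[lbl] for lbl in PROTEIN_BACKBONE]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Residue {self.mol_code} {self.insertion_id} ({len(self)} atoms)>"


class Polymer:
    """One chain: an ordered list of residues, N→C (protein) or 5′→3′ (nucleic)."""

    __slots__ = ("id", "residues", "polymer_type", "parent")

    def __init__(self, id: str = "A", residues: Iterable[Residue] = (),
                 polymer_type: str = "protein"):
        if polymer_type not in ("protein", "nucleic"):
            raise ValueError(f"unknown polymer_type {polymer_type!r}")
        self.id = id
        self.polymer_type = polymer_type
        self.residues: list[Residue] = []
        self.parent: "Assembly | None" = None
        for res in residues:
            self.add_residue(res)

    def add_residue(self, residue: Residue) -> None:
        residue.parent = self
        self.residues.append(residue)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, index: int) -> Residue:
        return self.residues[index]

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of all atom coordinates in hierarchy order."""
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        atoms = list(self.atoms())
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(atoms, coords):
            atom.coords = xyz

    def ca_coordinates(self) -> np.ndarray:
        out = []
        for res in self.residues:
            if "CA" not in res:
                raise ValueError(
                    f"residue {res.mol_code} {res.insertion_id} in chain "
                    f"{self.id} has no CA atom")
            out.append(res["CA"].coords)
        return np.array(out, dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Polymer {self.id} ({len(self)} residues, {self.polymer_type})>"


class Assembly:
    """An ordered collection of polymers with unique chain ids."""

    __slots__ = ("id", "polymers")

    def __init__(self, polymers: Iterable[Polymer] = (), id: str = "assembly"):
        self.id = id
        self.polymers: list[Polymer] = []
        for p in polymers:
            self.add_polymer(p)

    def add_polymer(self, polymer: Polymer) -> None:
        if any(p.id == polymer.id for p in self.polymers):
            raise ValueError(f"duplicate chain id {polymer.id!r}")
        polymer.parent = self
        self.polymers.append(polymer)

    def __iter__(self) -> Iterator[Polymer]:
        return iter(self.polymers)

    def __len__(self) -> int:
        return len(self.polymers)

    def __getitem__(self, key: int | str) -> Polymer:
        if isinstance(key, str):
            for p in self.polymers:
                if p.id == key:
                    return p
            raise KeyError(key)
        return self.polymers[key]

    def atoms(self) -> Iterator[Atom]:
        for p in self.polymers:
            yield from p.atoms()

    def residues(self) -> Iterator[Residue]:
        for p in self.polymers:
            yield from p

    def coordinates(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        atoms = list(self.atoms())
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, xyz in zip(atoms, coords):
            atom.coords = xyz

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def copy(self) -> "Assembly":
        new = Assembly(id=self.id)
        for p in self.polymers:
            np_ = Polymer(id=p.id, polymer_type=p.polymer_type)
            for r in p.residues:
                nr = Residue(r.mol_code, r.insertion_id)
                nr.tags = dict(r.tags)
                for a in r:
                    nr.add_atom(Atom(a.label, a.coords.copy(), a.element, a.serial))
                np_.add_residue(nr)
            new.add_polymer(np_)
        return new

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Assembly {self.id!r} ({len(self)} chains, {self.n_atoms()} atoms)>"


@dataclass
class Primitive:
    """Smoothed Cα trace of one polymer: an ordered list of 3-vectors (Å)."""

    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __len__(self) -> int:
        return len(self.points)


def primitive_of(chain: Polymer) -> Primitive:
    """Smoothed Cα trace: centered running mean of width 3, truncated at ends.

    Point 0 is the mean of the first two CA positions, the last point the
    mean of the final two; interior point ``i`` averages CA(i-1..i+1).  The
    output has one point per residue.
    """
    ca = chain.ca_coordinates()
    n = len(ca)
    if n < 3:
        raise ValueError(f"primitive requires >= 3 residues, got {n}")
    pts = np.empty_like(ca)
    pts[0] = ca[:2].mean(axis=0)
    pts[-1] = ca[-2:].mean(axis=0)
    for i in range(1, n - 1):
        pts[i] = ca[i - 1:i + 2].mean(axis=0)
    return Primitive(points=pts)


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0.0:
        raise ValueError("rotation axis must be non-zero")
    k = axis / norm
    theta = np.radians(angle_deg)
    kx, ky, kz = k
    cross = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return (np.cos(theta) * np.eye(3)
            + np.sin(theta) * cross
            + (1.0 - np.cos(theta)) * np.outer(k, k))


def _apply_to(target, func) -> None:
    if isinstance(target, Assembly):
        coords = target.coordinates()
        target.set_coordinates(func(coords))
    elif isinstance(target, Polymer):
        coords = target.coordinates()
        target.set_coordinates(func(coords))
    else:
        raise TypeError(f"cannot transform object of type {type(target).__name__}")


def rotate(target, axis, angle: float, point=(0.0, 0.0, 0.0)):
    """Rotate an assembly or polymer about the line through ``point`` along ``axis``.

    The rotation is right-handed about the axis direction; ``angle`` is in
    degrees.  Returns the same (mutated) object for chaining.
    """
    R = rotation_matrix(axis, angle)
    p = np.asarray(point, dtype=float)
    _apply_to(target, lambda c: (c - p) @ R.T + p)
    return target


def translate(target, vector):
    """Shift every atom of an assembly or polymer by ``vector`` (Å)."""
    v = np.asarray(vector, dtype=float)
    _apply_to(target, lambda c: c + v)
    return target


def relabel(assembly: Assembly) -> Assembly:
    """Relabel chains A, B, C, …, renumber residues from 1 per chain and
    renumber atom serials sequentially from 1 across the assembly (in place)."""
    if len(assembly) > len(CHAIN_ALPHABET):
        raise ValueError(
            f"cannot relabel {len(assembly)} chains: only "
            f"{len(CHAIN_ALPHABET)} single-character ids available")
    serial = 1
    for chain, new_id in zip(assembly, CHAIN_ALPHABET):
        chain.id = new_id
        for i, res in enumerate(chain, start=1):
            res.insertion_id = str(i)
            for atom in res:
                atom.serial = serial
                serial += 1
    return assembly
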