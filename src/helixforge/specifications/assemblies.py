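"""Assembly-level fold specifications.

These arrange polymer-level helix builds into quaternary folds:

* ``build_coiled_coil`` — n helices supercoiled about a common axis with
  n-fold rotational symmetry (Crick parameterization: superhelix radius,
  pitch and interface angle φCα, plus per-chain z-shifts and rotations);
* ``build_tropocollagen`` — the same specification with polyproline-II
  strands, a right-handed superhelix and per-chain z-shifts producing
  the leading/lagging strand stagger of the collagen triple helix;
* ``build_helix_pair`` — two α-helices placed independently about a
  reference axis (the repeating unit of α-solenoids);
* ``build_solenoid`` — any repeat unit replicated by a fixed screw
  transform (radius, rise per repeat, twist per repeat, handedness).

All protein builders emit glycine backbones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..core import Assembly, relabel, rotate, rotation_matrix, translate
from .constants import ALPHA, DEFAULT_BOND_GEOMETRY, PPII, HelixClass
from .helices import (build_helical_helix, build_helix, helical_helix_coords,
                      helix_coords, reference_geometry)

__all__ = ["CrickParams", "HelixPairParams", "SolenoidParams",
           "build_coiled_coil", "build_tropocollagen", "build_helix_pair",
           "build_solenoid", "coiled_coil_coords", "helix_pair_coords",
           "solenoid_coords", "canonicalize_unit"]


def _per_chain(value, n: int, name: str) -> list:
    """Broadcast a scalar to n chains, or validate a length-n sequence."""
    if np.isscalar(value) or isinstance(value, str):
        return [value] * n
    value = list(value)
    if len(value) != n:
        raise ValueError(f"{name} must have one entry per chain "
                         f"({n}), got {len(value)}")
    return value


@dataclass
class CrickParams:
    """Crick-style coiled-coil parameters.

    ``superhelix_radius`` (Å), ``pitch`` (Å) and ``interface_angle``
    (φCα, degrees) are the three core structural parameters; ``z_shift``
    and ``chain_rotation`` may be scalars or per-chain sequences.
    ``orientation`` entries are "parallel" or "antiparallel".
    """

    n_chains: int = 2
    superhelix_radius: float = 5.0
    pitch: float = 150.0
    interface_angle: float = 0.0
    n_residues: int | Sequence[int] = 28
    z_shift: float | Sequence[float] = 0.0
    chain_rotation: float | Sequence[float] = 0.0
    orientation: str | Sequence[str] = "parallel"
    superhelix_handedness: str = "left"

    def validate(self) -> None:
        if self.n_chains < 2:
            raise ValueError(f"n_chains must be >= 2, got {self.n_chains}")
        if self.superhelix_radius <= 0:
            raise ValueError(
                f"superhelix_radius must be > 0, got {self.superhelix_radius}")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.superhelix_handedness not in ("left", "right"):
            raise ValueError("superhelix_handedness must be 'left' or 'right'")
        for n in _per_chain(self.n_residues, self.n_chains, "n_residues"):
            if n < 2:
                raise ValueError(f"n_residues must be >= 2, got {n}")
        for o in _per_chain(self.orientation, self.n_chains, "orientation"):
            if o not in ("parallel", "antiparallel"):
                raise ValueError(f"orientation must be 'parallel' or "
                                 f"'antiparallel', got {o!r}")


def coiled_coil_coords(p: CrickParams, cls: HelixClass = ALPHA) -> list:
    """Per-chain (n_res, 4, 3) backbone coordinate arrays of a coiled coil.

    Chain k is phase-shifted by k·360/n about the superhelix axis,
    rotated about its own path by its ``chain_rotation`` and shifted
    along z by its ``z_shift``.  This is the array-level core of
    :func:`build_coiled_coil`.
    """
    p.validate()
    ref = reference_geometry(cls, DEFAULT_BOND_GEOMETRY)
    n = p.n_chains
    n_res = _per_chain(p.n_residues, n, "n_residues")
    z_shifts = _per_chain(p.z_shift, n, "z_shift")
    rotations = _per_chain(p.chain_rotation, n, "chain_rotation")
    orientations = _per_chain(p.orientation, n, "orientation")

    chains = []
    for k in range(n):
        coords = helical_helix_coords(
            ref, int(n_res[k]),
            r0=p.superhelix_radius, pitch=p.pitch,
            phase=k * 360.0 / n,
            handedness=p.superhelix_handedness,
            phi_ca=p.interface_angle + float(rotations[k]))
        if orientations[k] == "antiparallel":
            # Negate the chain's axis direction (proper rotation about x,
            # preserving chirality), restoring its angular position.
            R = (rotation_matrix((0.0, 0.0, 1.0), 2.0 * k * 360.0 / n)
                 @ rotation_matrix((1.0, 0.0, 0.0), 180.0))
            coords = coords @ R.T
        coords = coords + np.array([0.0, 0.0, float(z_shifts[k])])
        chains.append(coords)
    return chains


def build_coiled_coil(p: CrickParams, cls: HelixClass = ALPHA) -> Assembly:
    """Build an n-chain coiled coil with n-fold symmetry about the z-axis."""
    from .helices import _glycine_chain

    assembly = Assembly(id="coiled_coil")
    for k, coords in enumerate(coiled_coil_coords(p, cls)):
        chain = _glycine_chain(coords, chain_id="_tmp%d" % k)
        assembly.add_polymer(chain)
    return relabel(assembly)


def build_tropocollagen(p: CrickParams, cls: HelixClass = PPII) -> Assembly:
    """Collagen triple helix: three PPII strands on a right-handed superhelix.

    Per-chain ``z_shift`` values produce the leading/lagging strand
    stagger characteristic of tropocollagen.
    """
    if p.n_chains != 3:
        raise ValueError(
            f"tropocollagen requires exactly 3 chains, got {p.n_chains}")
    p.validate()
    return build_coiled_coil(p, cls)


@dataclass
class HelixPairParams:
    """Two α-helices placed independently about a reference (z) axis.

    Per-helix parameters (each a 2-sequence): ``axis_distance`` (Å from
    the reference axis; the two helices sit on opposite sides of it),
    ``z_shift`` (Å along the axis), ``phi_ca`` (spin of the helix about
    its own axis, degrees), ``splay`` (in-plane tilt, degrees) and
    ``off_plane_rotation`` (rotation about the radial direction,
    degrees; 180° points the helix antiparallel to the reference axis).
    ``helix_lengths`` are the residue counts.
    """

    axis_distance: Sequence[float] = (3.0, 3.0)
    z_shift: Sequence[float] = (0.0, 0.0)
    phi_ca: Sequence[float] = (0.0, 0.0)
    splay: Sequence[float] = (0.0, 0.0)
    off_plane_rotation: Sequence[float] = (0.0, 0.0)
    helix_lengths: Sequence[int] = (10, 10)

    def validate(self) -> None:
        for name in ("axis_distance", "z_shift", "phi_ca", "splay",
                     "off_plane_rotation", "helix_lengths"):
            v = getattr(self, name)
            if np.isscalar(v) or len(list(v)) != 2:
                raise ValueError(f"{name} must be a 2-sequence (two helices)")
        for L in self.helix_lengths:
            if L < 2:
                raise ValueError(f"helix length must be >= 2, got {L}")


# Sides of the reference axis on which the two helices are placed.
_PAIR_SIDES = (1.0, -1.0)


def helix_pair_coords(p: HelixPairParams, cls: HelixClass = ALPHA) -> list:
    """Per-helix (n_res, 4, 3) coordinate arrays of a two-helix unit."""
    p.validate()
    ref = reference_geometry(cls, DEFAULT_BOND_GEOMETRY)
    chains = []
    for j in range(2):
        coords = helix_coords(ref, int(p.helix_lengths[j]),
                              phase=float(p.phi_ca[j]))
        coords = coords - coords.reshape(-1, 3).mean(axis=0)
        R = (rotation_matrix((1.0, 0.0, 0.0), float(p.off_plane_rotation[j]))
             @ rotation_matrix((0.0, 1.0, 0.0), float(p.splay[j])))
        coords = coords @ R.T
        coords = coords + np.array([
            _PAIR_SIDES[j] * float(p.axis_distance[j]), 0.0,
            float(p.z_shift[j])])
        chains.append(coords)
    return chains


def build_helix_pair(p: HelixPairParams, cls: HelixClass = ALPHA) -> Assembly:
    """Build the two-helix repeating unit of a solenoid.

    Each helix is built along +z centred on the origin, spun by its
    ``phi_ca`` about its own axis, tilted in-plane (about y) by
    ``splay``, rotated out-of-plane (about x, the radial direction) by
    ``off_plane_rotation``, then moved to its signed ``axis_distance``
    along x and its ``z_shift`` along z.
    """
    from .helices import _glycine_chain

    assembly = Assembly(id="helix_pair")
    for j, coords in enumerate(helix_pair_coords(p, cls)):
        assembly.add_polymer(_glycine_chain(coords, chain_id="_tmp%d" % j))
    return relabel(assembly)


@dataclass
class SolenoidParams:
    """Helical-symmetry replication of a repeat unit.

    ``repeat_unit`` is an Assembly (or HelixPairParams from which one is
    built).  The unit is canonicalized (centroid at the origin,
    principal axes aligned with the coordinate axes), rotated by
    ``unit_rotation`` about the radial (x) direction, placed at
    ``radius`` from the solenoid (z) axis, then copied ``n_repeats``
    times, each copy advanced by ``rise_per_repeat`` along the axis and
    ``twist_per_repeat`` about it (sign per ``handedness``).
    """

    repeat_unit: "Assembly | HelixPairParams" = field(
        default_factory=HelixPairParams)
    n_repeats: int = 4
    radius: float = 30.0
    rise_per_repeat: float = 10.0
    twist_per_repeat: float = 10.0
    handedness: str = "right"
    unit_rotation: float = 0.0

    def validate(self) -> None:
        if self.n_repeats < 2:
            raise ValueError(f"n_repeats must be >= 2, got {self.n_repeats}")
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.handedness not in ("left", "right"):
            raise ValueError("handedness must be 'left' or 'right'")


def canonicalize_unit(unit: Assembly) -> Assembly:
    """Centre a repeat unit and align its principal axes with x, y, z.

    The longest principal axis maps to z, the shortest to x (the radial
    direction).  Signs are fixed deterministically so that rigidly
    transformed copies of the same unit canonicalize identically.
    """
    unit = unit.copy()
    coords = unit.coordinates()
    centroid = coords.mean(axis=0)
    coords = coords - centroid
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    axes = vt.copy()  # rows: principal axes, largest spread first
    # Fix signs: each axis points so the most distal atom has positive
    # projection; then enforce a right-handed frame.
    for i in range(3):
        proj = coords @ axes[i]
        if proj[np.argmax(np.abs(proj))] < 0:
            axes[i] = -axes[i]
    if np.linalg.det(axes) < 0:
        axes[1] = -axes[1]
    # Map: first principal axis -> z, second -> y, third -> x.
    R = axes[::-1]  # rows now x', y', z' directions
    if np.linalg.det(R) < 0:
        R = R.copy()
        R[1] = -R[1]
    unit.set_coordinates(coords @ R.T)
    return unit


def solenoid_coords(unit_coords: np.ndarray, p: SolenoidParams) -> np.ndarray:
    """(n_repeats · n_unit, 3) coordinates of a solenoid from an already
    canonicalized repeat-unit coordinate array."""
    coords = unit_coords @ rotation_matrix(
        (1.0, 0.0, 0.0), float(p.unit_rotation)).T
    coords = coords + np.array([float(p.radius), 0.0, 0.0])
    sign = 1.0 if p.handedness == "right" else -1.0
    out = []
    for i in range(p.n_repeats):
        R = rotation_matrix((0.0, 0.0, 1.0), sign * i * float(p.twist_per_repeat))
        out.append(coords @ R.T + np.array([0.0, 0.0,
                                            i * float(p.rise_per_repeat)]))
    return np.concatenate(out, axis=0)


def build_solenoid(p: SolenoidParams, cls: HelixClass = ALPHA) -> Assembly:
    """Replicate a repeat unit with a fixed screw transform."""
    p.validate()
    if isinstance(p.repeat_unit, HelixPairParams):
        unit = build_helix_pair(p.repeat_unit, cls)
    else:
        unit = p.repeat_unit
    unit = canonicalize_unit(unit)
    rotate(unit, (1.0, 0.0, 0.0), float(p.unit_rotation))
    translate(unit, (float(p.radius), 0.0, 0.0))
    sign = 1.0 if p.handedness == "right" else -1.0

    assembly = Assembly(id="solenoid")
    for i in range(p.n_repeats):
        copy = unit.copy()
        rotate(copy, (0.0, 0.0, 1.0), sign * i * float(p.twist_per_repeat))
        translate(copy, (0.0, 0.0, i * float(p.rise_per_repeat)))
        for chain in copy:
            chain.id = f"_tmp{i}_{chain.id}"
            chain.parent = None
            assembly.add_polymer(chain)
    return relabel(assembly)
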