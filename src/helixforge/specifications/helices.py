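"""Path-following helix builders.

``build_helix`` winds an ideal helix of a given class about a straight
axis; ``build_helical_helix`` winds the same local geometry along a
superhelical (Crick-style) path of given radius and pitch.

Both place all four backbone atoms per residue.  The positions of N, C
and O relative to the Cα path are taken from a torsion-built reference
helix of the same class: the reference is screw-decomposed and each atom
type's cylinder radius, phase offset and axial offset relative to Cα are
reused.  On a straight axis this reproduces the torsion-angle route
exactly; along a supercoiled path the local frame follows the path, with
the minor-helix phase corrected for the path's intrinsic frame rotation
(its torsion) so that local geometry is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ..core import Atom, Polymer, Residue, rotation_matrix
from .constants import (BondGeometry, DEFAULT_BOND_GEOMETRY, HelixClass)

__all__ = ["reference_geometry", "build_helix", "build_helical_helix",
           "helix_coords", "helical_helix_coords",
           "ReferenceGeometry", "BACKBONE_LABELS"]

BACKBONE_LABELS = ("N", "CA", "C", "O")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


@dataclass(frozen=True)
class ReferenceGeometry:
    """Screw parameters of an ideal helix and per-atom cylinder offsets.

    ``twist`` is the signed twist per residue in degrees (+ = right-
    handed), ``rise`` the rise per residue in Å.  ``offsets`` maps each
    backbone atom label to (cylinder radius, phase offset in degrees
    relative to Cα, axial offset in Å relative to Cα).
    """

    twist: float
    rise: float
    offsets: dict


@lru_cache(maxsize=32)
def reference_geometry(cls: HelixClass,
                       geom: BondGeometry = DEFAULT_BOND_GEOMETRY,
                       n_ref: int = 24) -> ReferenceGeometry:
    """Derive a helix class's screw geometry from its canonical torsions."""
    from ..geometry import superpose
    from .torsion import build_ta_polypeptide

    t = cls.canonical_torsions
    poly = build_ta_polypeptide([t] * n_ref, geom)
    res = poly.residues
    a = np.array([res[i][lbl].coords
                  for i in range(n_ref - 1) for lbl in BACKBONE_LABELS])
    b = np.array([res[i][lbl].coords
                  for i in range(1, n_ref) for lbl in BACKBONE_LABELS])
    sp = superpose(a, b)  # the i -> i+1 screw transform
    R, tvec = sp.rotation, sp.translation

    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    rise = float(tvec @ axis)
    if rise < 0:
        axis, rise = -axis, -rise
    # Signed rotation angle about the (rise-positive) axis.
    u = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
    if np.linalg.norm(u) < 1e-8:
        u = np.array([0.0, 1.0, 0.0]) - axis[1] * axis
    u /= np.linalg.norm(u)
    ru = R @ u
    twist = float(np.degrees(np.arctan2(np.cross(u, ru) @ axis, u @ ru)))
    # A point on the screw axis: (R - I) p = rise*axis - t.
    p0 = np.linalg.lstsq(R - np.eye(3), rise * axis - tvec, rcond=None)[0]

    m = n_ref // 2
    d_ca = res[m]["CA"].coords - p0
    z_ca = d_ca @ axis
    rad_ca = d_ca - z_ca * axis
    e_r = rad_ca / np.linalg.norm(rad_ca)
    e_t = np.cross(axis, e_r)
    offsets = {}
    for lbl in BACKBONE_LABELS:
        d = res[m][lbl].coords - p0
        z = d @ axis
        rad = d - z * axis
        offsets[lbl] = (float(np.linalg.norm(rad)),
                        float(np.degrees(np.arctan2(rad @ e_t, rad @ e_r))),
                        float(z - z_ca))
    return ReferenceGeometry(twist=twist, rise=rise, offsets=offsets)


def _glycine_chain(coords: np.ndarray, chain_id: str = "A") -> Polymer:
    """Wrap an (n_res, 4, 3) backbone coordinate array as a glycine chain."""
    poly = Polymer(id=chain_id, polymer_type="protein")
    for i, atom_coords in enumerate(coords, start=1):
        res = Residue("GLY", insertion_id=str(i))
        for lbl, xyz in zip(BACKBONE_LABELS, atom_coords):
            res.add_atom(Atom(lbl, xyz, element=_ELEMENTS[lbl]))
        poly.add_residue(res)
    return poly


def helix_coords(ref: ReferenceGeometry, n_res: int,
                 phase: float = 0.0) -> np.ndarray:
    """(n_res, 4, 3) backbone coordinates of a straight helix along +z."""
    i = np.arange(n_res)[:, None]                      # residues
    r_k = np.array([ref.offsets[l][0] for l in BACKBONE_LABELS])
    dth = np.array([ref.offsets[l][1] for l in BACKBONE_LABELS])
    dz = np.array([ref.offsets[l][2] for l in BACKBONE_LABELS])
    th = np.radians(phase + i * ref.twist + dth)       # (n_res, 4)
    out = np.empty((n_res, 4, 3))
    out[:, :, 0] = r_k * np.cos(th)
    out[:, :, 1] = r_k * np.sin(th)
    out[:, :, 2] = i * ref.rise + dz
    return out


def helical_helix_coords(ref: ReferenceGeometry, n_res: int, r0: float,
                         pitch: float, phase: float = 0.0,
                         handedness: str = "left",
                         phi_ca: float = 0.0) -> np.ndarray:
    """(n_res, 4, 3) backbone coordinates of a supercoiled helix.

    Same construction as :func:`build_helical_helix`, vectorized; see
    that function for the geometry and conventions.
    """
    sigma = 1.0 if handedness == "right" else -1.0
    k = sigma * 2.0 * np.pi / pitch
    lam = np.sqrt(1.0 + (2.0 * np.pi * r0 / pitch) ** 2)
    omega_frame = k / lam ** 2
    i = np.arange(n_res)[:, None]
    r_k = np.array([ref.offsets[l][0] for l in BACKBONE_LABELS])
    dth = np.array([ref.offsets[l][1] for l in BACKBONE_LABELS])
    dz = np.array([ref.offsets[l][2] for l in BACKBONE_LABELS])

    s = i * ref.rise + dz                              # (n_res, 4) arc length
    z = s / lam
    phi = np.radians(phase) + k * z
    cphi, sphi = np.cos(phi), np.sin(phi)
    psi = np.radians(phi_ca + i * ref.twist + dth) - omega_frame * s
    cpsi, spsi = np.cos(psi), np.sin(psi)
    # n_hat = (-cphi, -sphi, 0); b_hat = t_hat x n_hat = (sphi, -cphi, r0*k)/lam
    out = np.empty((n_res, 4, 3))
    out[:, :, 0] = r0 * cphi + r_k * (-cphi * cpsi + sphi * spsi / lam)
    out[:, :, 1] = r0 * sphi + r_k * (-sphi * cpsi - cphi * spsi / lam)
    out[:, :, 2] = z + r_k * spsi * (r0 * k / lam)
    return out


def build_helix(cls: HelixClass, n_res: int, start=(0.0, 0.0, 0.0),
                end=None, phase: float = 0.0,
                geom: BondGeometry = DEFAULT_BOND_GEOMETRY) -> Polymer:
    """Build an ideal glycine-backbone helix about the start→end axis.

    Cα atoms lie on a circular helix of the class's radius about the
    axis, with the class's per-residue rise and twist.  ``phase``
    (degrees) rotates the helix about its own axis; at phase 0 the first
    Cα lies in the +x half-plane when the axis is +z.
    """
    if n_res < 2:
        raise ValueError(f"a helix needs at least 2 residues, got {n_res}")
    ref = reference_geometry(cls, geom)
    start = np.asarray(start, dtype=float)
    if end is None:
        direction = np.array([0.0, 0.0, 1.0])
    else:
        end = np.asarray(end, dtype=float)
        direction = end - start
        if np.linalg.norm(direction) < 1e-9:
            raise ValueError("start and end coincide: axis undefined")
        direction = direction / np.linalg.norm(direction)

    poly = _glycine_chain(helix_coords(ref, n_res, phase))
    _orient_z_to(poly, direction, start)
    return poly


def _orient_z_to(poly: Polymer, direction: np.ndarray, origin: np.ndarray) -> None:
    """Rotate a z-built polymer so +z maps to ``direction``, then shift to origin."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(z @ direction, -1.0, 1.0))
    coords = poly.coordinates()
    if c < 1.0 - 1e-12:
        if c > -1.0 + 1e-12:
            axis = np.cross(z, direction)
        else:
            axis = np.array([1.0, 0.0, 0.0])  # antiparallel: flip about x
        R = rotation_matrix(axis, float(np.degrees(np.arccos(c))))
        coords = coords @ R.T
    poly.set_coordinates(coords + origin)


def build_helical_helix(cls: HelixClass, n_res: int, r0: float, pitch: float,
                        phase: float = 0.0, handedness: str = "left",
                        phi_ca: float = 0.0,
                        geom: BondGeometry = DEFAULT_BOND_GEOMETRY) -> Polymer:
    """Wind a helix of class ``cls`` along a superhelical path (z-axis).

    The path has radius ``r0`` and pitch ``pitch`` (both Å, > 0);
    ``handedness`` is the chirality of the *superhelix*.  ``phase``
    (degrees) sets the start angle of the path around the z-axis.
    ``phi_ca`` is the interface angle: the rotation of the minor helix
    about its own path tangent, with zero meaning the first residue's Cα
    points toward the superhelix axis.

    Residues advance along the path at the class's rise per residue in
    arc length, and the minor-helix phase is corrected for the path's
    frame rotation (torsion) so local helical geometry is preserved.
    """
    if n_res < 2:
        raise ValueError(f"a helix needs at least 2 residues, got {n_res}")
    if r0 <= 0 or pitch <= 0:
        raise ValueError("superhelix radius and pitch must be positive")
    if handedness not in ("left", "right"):
        raise ValueError("handedness must be 'left' or 'right'")
    ref = reference_geometry(cls, geom)
    return _glycine_chain(
        helical_helix_coords(ref, n_res, r0, pitch, phase, handedness, phi_ca))
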