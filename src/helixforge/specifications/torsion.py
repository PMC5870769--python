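"""Torsion-angle polypeptide building.

Backbones are grown atom-by-atom with sequential internal-to-Cartesian
placement (natural extension reference frame): each new atom is placed
from the previous three using a bond length, a bond angle and a torsion
angle.  Measured torsions of the output reproduce the inputs exactly (up
to floating-point error), which the tests use as the self-consistency
check.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ..core import Atom, Polymer, Residue
from .constants import BondGeometry, DEFAULT_BOND_GEOMETRY, TorsionTriple

__all__ = ["place_atom", "build_ta_polypeptide", "backbone_torsions"]


def place_atom(a, b, c, bond: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom D so that |C−D| = bond, angle(B,C,D) = angle_deg and the
    torsion A-B-C-D equals torsion_deg (IUPAC sign convention)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_ta_polypeptide(torsions: Sequence[TorsionTriple],
                         geom: BondGeometry = DEFAULT_BOND_GEOMETRY,
                         mol_code: str = "GLY") -> Polymer:
    """Build a glycine backbone from per-residue (φ, ψ, ω) triples.

    φ of the first residue is undefined (no preceding C) and is ignored;
    ψ and ω of the last residue only orient its carbonyl oxygen.
    """
    torsions = list(torsions)
    if len(torsions) < 2:
        raise ValueError("need at least 2 torsion triples")
    geom.validate()

    # Seed residue 0 in the xy-plane.
    n0 = np.zeros(3)
    ca0 = np.array([geom.n_ca, 0.0, 0.0])
    ang = np.radians(geom.n_ca_c)
    c0 = ca0 + geom.ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])

    n_xyz = [n0]
    ca_xyz = [ca0]
    c_xyz = [c0]
    for i in range(1, len(torsions)):
        prev = i - 1
        n_next = place_atom(n_xyz[prev], ca_xyz[prev], c_xyz[prev],
                            geom.c_n, geom.ca_c_n, torsions[prev].psi)
        ca_next = place_atom(ca_xyz[prev], c_xyz[prev], n_next,
                             geom.n_ca, geom.c_n_ca, torsions[prev].omega)
        c_next = place_atom(c_xyz[prev], n_next, ca_next,
                            geom.ca_c, geom.n_ca_c, torsions[i].phi)
        n_xyz.append(n_next)
        ca_xyz.append(ca_next)
        c_xyz.append(c_next)

    polymer = Polymer(id="A", polymer_type="protein")
    for i, triple in enumerate(torsions):
        # Carbonyl O sits in the peptide plane, anti to the next N.
        o = place_atom(n_xyz[i], ca_xyz[i], c_xyz[i],
                       geom.c_o, geom.ca_c_o, triple.psi + 180.0)
        res = Residue(mol_code, insertion_id=str(i + 1))
        res.add_atom(Atom("N", n_xyz[i], element="N"))
        res.add_atom(Atom("CA", ca_xyz[i], element="C"))
        res.add_atom(Atom("C", c_xyz[i], element="C"))
        res.add_atom(Atom("O", o, element="O"))
        polymer.add_residue(res)
    return polymer


def backbone_torsions(polymer: Polymer) -> list[dict]:
    """Measure (φ, ψ, ω) for every residue of a backbone-complete chain.

    Returns one dict per residue with keys "phi", "psi", "omega"; values
    are ``None`` where the angle is undefined (chain termini).
    """
    from ..geometry import dihedral

    res = polymer.residues
    out = []
    for i, r in enumerate(res):
        entry = {"phi": None, "psi": None, "omega": None}
        if i > 0:
            entry["phi"] = dihedral(res[i - 1]["C"].coords, r["N"].coords,
                                    r["CA"].coords, r["C"].coords)
        if i < len(res) - 1:
            entry["psi"] = dihedral(r["N"].coords, r["CA"].coords,
                                    r["C"].coords, res[i + 1]["N"].coords)
            entry["omega"] = dihedral(r["CA"].coords, r["C"].coords,
                                      res[i + 1]["N"].coords,
                                      res[i + 1]["CA"].coords)
        out.append(entry)
    return out
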