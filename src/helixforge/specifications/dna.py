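"""Ideal B-form DNA duplex builder.

Base pairs are generated from a synthetic idealized template: a planar
Watson–Crick pair with C1′, the sugar–phosphate backbone trace
(P, O5′, C5′, C4′, C3′, O3′) and base ring atoms at idealized fiber-
model-like positions.  The template is constructed geometrically in
code, not copied from any experimental structure, so base geometry is
approximate; the duplex-level parameters — rise and twist per base
pair, antiparallel strand topology — are exact.

Pairs are stacked along the z-axis with ``rise_per_bp`` and rotated by
``twist_per_bp`` per step (right-handed).  Strand 2 is the reverse
complement of strand 1 and runs antiparallel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Assembly, Atom, Polymer, Residue, rotation_matrix
from .constants import DNA_RISE_PER_BP, DNA_TWIST_PER_BP

__all__ = ["DnaDuplexParams", "build_dna_duplex", "reverse_complement"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PURINES = {"A", "G"}


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence))


@dataclass
class DnaDuplexParams:
    """Sequence (5′→3′ of strand 1, over A/C/G/T) plus duplex geometry."""

    sequence: str = "GATTACA"
    rise_per_bp: float = DNA_RISE_PER_BP
    twist_per_bp: float = DNA_TWIST_PER_BP

    def validate(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("sequence must contain at least 2 bases")
        for i, b in enumerate(self.sequence):
            if b not in _COMPLEMENT:
                raise ValueError(
                    f"invalid base {b!r} at position {i + 1}: "
                    f"sequence must be over A, C, G, T")


def _strand_template(base: str) -> list[tuple[str, np.ndarray]]:
    """Idealized planar atom positions for one nucleotide of strand 1.

    Synthetic template: atoms are placed in the z = 0 base-pair plane.
    The backbone trace sits near 9 Å from the helix axis around azimuth
    ~+70°; the base extends inward from C1′ toward the axis.
    """
    def cyl(r, az_deg, z=0.0):
        a = np.radians(az_deg)
        return np.array([r * np.cos(a), r * np.sin(a), z])

    atoms = [
        ("P", cyl(9.4, 76.0, 1.9)),
        ("O5'", cyl(9.1, 71.0, 1.2)),
        ("C5'", cyl(9.2, 66.0, 0.6)),
        ("C4'", cyl(8.8, 62.0, 0.0)),
        ("C3'", cyl(8.9, 57.0, -0.7)),
        ("O3'", cyl(9.3, 52.0, -1.3)),
        ("C1'", cyl(5.9, 62.0, 0.0)),
    ]
    # Base ring: a planar ring trace running inward from C1' toward the
    # helix axis.  Purines get a 9-atom two-ring trace, pyrimidines 6.
    if base in _PURINES:
        ring = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
        radii = [4.6, 4.5, 3.5, 3.1, 2.2, 1.1, 0.9, 1.9, 3.2]
        azim = [58.0, 72.0, 74.0, 58.0, 62.0, 52.0, 36.0, 30.0, 42.0]
    else:
        ring = ["N1", "C2", "N3", "C4", "C5", "C6"]
        radii = [4.6, 3.6, 2.8, 3.0, 4.1, 4.7]
        azim = [58.0, 46.0, 54.0, 70.0, 78.0, 72.0]
    for lbl, r, az in zip(ring, radii, azim):
        atoms.append((lbl, cyl(r, az)))
    return atoms


def _paired_template(base: str) -> list[tuple[str, np.ndarray]]:
    """Strand-2 partner atoms: the complement base's template rotated
    180° about the in-plane dyad (x) axis — antiparallel by construction."""
    R = rotation_matrix((1.0, 0.0, 0.0), 180.0)
    return [(lbl, R @ xyz) for lbl, xyz in _strand_template(_COMPLEMENT[base])]


def build_dna_duplex(p: DnaDuplexParams) -> Assembly:
    """Build an ideal antiparallel DNA duplex along the z-axis."""
    p.validate()
    n = len(p.sequence)
    twist = float(p.twist_per_bp)
    rise = float(p.rise_per_bp)

    def placed(template, i):
        R = rotation_matrix((0.0, 0.0, 1.0), i * twist)
        shift = np.array([0.0, 0.0, i * rise])
        return [(lbl, R @ xyz + shift) for lbl, xyz in template]

    strand1 = Polymer(id="A", polymer_type="nucleic")
    for i, base in enumerate(p.sequence):
        res = Residue("D" + base, insertion_id=str(i + 1))
        for lbl, xyz in placed(_strand_template(base), i):
            res.add_atom(Atom(lbl, xyz, element=lbl[0]))
        strand1.add_residue(res)

    strand2 = Polymer(id="B", polymer_type="nucleic")
    # 5'->3' of strand 2 runs from the last base pair back to the first.
    for j, base2 in enumerate(reverse_complement(p.sequence)):
        i = n - 1 - j               # base-pair index this residue pairs in
        base1 = p.sequence[i]
        res = Residue("D" + base2, insertion_id=str(j + 1))
        for lbl, xyz in placed(_paired_template(base1), i):
            res.add_atom(Atom(lbl, xyz, element=lbl[0]))
        strand2.add_residue(res)

    assembly = Assembly(id="dna_duplex")
    assembly.add_polymer(strand1)
    assembly.add_polymer(strand2)
    return assembly
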