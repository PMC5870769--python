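"""Idealized geometric constants used by the parametric builders.

Each helix class is defined by its canonical backbone torsion angles
(φ, ψ); the cylinder the Cα trace winds around — rise per residue,
radius, residues per turn, handedness — is *derived* from those torsions
by screw-decomposing a torsion-built reference helix.  Deriving rather
than declaring the cylinder constants keeps the two construction routes
(path-following and torsion-angle building) exactly consistent and
guarantees peptide-bond continuity in every built model.

The values are standard idealized geometry, not measurements from any
particular structure.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HelixClass", "BondGeometry", "TorsionTriple", "HELIX_CLASSES",
           "ALPHA", "PI", "PPII", "DEFAULT_BOND_GEOMETRY",
           "DNA_RISE_PER_BP", "DNA_TWIST_PER_BP"]


@dataclass(frozen=True)
class TorsionTriple:
    """One residue's backbone torsion angles (degrees, each in (−180, 180])."""

    phi: float
    psi: float
    omega: float = 180.0

    def __post_init__(self):
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} = {v} outside (-180, 180]")


@dataclass(frozen=True)
class BondGeometry:
    """Backbone bond lengths (Å) and angles (degrees)."""

    n_ca: float = 1.47
    ca_c: float = 1.53
    c_n: float = 1.33
    c_o: float = 1.24
    n_ca_c: float = 110.0
    ca_c_n: float = 114.0
    c_n_ca: float = 121.0
    ca_c_o: float = 121.0

    def validate(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "c_o"):
            v = getattr(self, name)
            if not (0.8 < v < 2.0):
                raise ValueError(f"bond length {name} = {v} outside (0.8, 2.0) Å")
        for name in ("n_ca_c", "ca_c_n", "c_n_ca", "ca_c_o"):
            v = getattr(self, name)
            if not (90.0 < v < 140.0):
                raise ValueError(f"bond angle {name} = {v} outside (90, 140)°")


DEFAULT_BOND_GEOMETRY = BondGeometry()


@dataclass(frozen=True)
class HelixClass:
    """An idealized polypeptide helix type, defined by canonical torsions.

    ``rise_per_residue`` (Å), ``helix_radius`` (Å of the Cα cylinder),
    ``residues_per_turn`` and ``handedness`` are derived from the
    canonical (φ, ψ) by screw decomposition of a reference helix built
    with the default bond geometry.
    """

    name: str
    canonical_torsions: TorsionTriple

    def _screw(self):
        from .helices import reference_geometry
        return reference_geometry(self, DEFAULT_BOND_GEOMETRY)

    @property
    def rise_per_residue(self) -> float:
        return self._screw().rise

    @property
    def helix_radius(self) -> float:
        return self._screw().offsets["CA"][0]

    @property
    def residues_per_turn(self) -> float:
        return 360.0 / abs(self._screw().twist)

    @property
    def handedness(self) -> str:
        return "right" if self._screw().twist > 0 else "left"

    @property
    def twist_per_residue(self) -> float:
        """Signed twist per residue in degrees (+ right-handed)."""
        return self._screw().twist


ALPHA = HelixClass("alpha", TorsionTriple(-57.8, -47.0))
PI = HelixClass("pi", TorsionTriple(-57.0, -70.0))
PPII = HelixClass("ppii", TorsionTriple(-75.0, 145.0))

HELIX_CLASSES = {"alpha": ALPHA, "pi": PI, "ppii": PPII}

# B-form DNA fiber-model defaults.
DNA_RISE_PER_BP = 3.38  # Å
DNA_TWIST_PER_BP = 34.3  # degrees per base pair
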