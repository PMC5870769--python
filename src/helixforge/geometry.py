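"""Superposition and structural-similarity measures.

The fitness used everywhere in parameter fitting is the backbone RMSD
after optimal rigid superposition.  Superposition uses the Kabsch (SVD)
formulation with reflection correction, which minimizes the same RMSD as
the classic least-squares methods.  RMSD₁₀₀ normalizes an RMSD to a
100-residue reference length so fits of different-sized structures can
be compared:

    RMSD₁₀₀ = RMSD / (1 + ln √(N/100))

The denominator vanishes as N → 100/e² ≈ 13.5, so the function is only
defined for comfortably larger N (we require N ≥ 20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Assembly, PROTEIN_BACKBONE

__all__ = [
    "SuperpositionResult",
    "RmsdReport",
    "superpose",
    "backbone_rmsd",
    "backbone_coordinates",
    "rmsd100",
    "dihedral",
    "fit_axis",
    "coordinate_rmsd",
]

RMSD100_MIN_RESIDUES = 20


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body superposition of a mobile onto a reference set.

    ``rotation`` (3×3, det = +1) and ``translation`` map mobile
    coordinates onto the reference frame: ``x ↦ rotation @ x + translation``.
    ``rmsd`` is the minimized root-mean-square deviation in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class RmsdReport:
    rmsd: float
    n_atoms: int
    rmsd100: float | None = None


def superpose(mobile, reference) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch algorithm).

    Finds the proper rotation + translation minimizing the RMSD over the
    1:1 point correspondence and returns it with the minimized RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape:
        raise ValueError(
            f"point sets differ in length: {len(mob)} vs {len(ref)}")
    if mob.ndim != 2 or mob.shape[1] != 3 or len(mob) < 3:
        raise ValueError("superposition needs >= 3 points of dimension 3")
    if not (np.all(np.isfinite(mob)) and np.all(np.isfinite(ref))):
        raise ValueError("non-finite coordinates")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    m0 = mob - mc
    r0 = ref - rc
    H = m0.T @ r0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = m0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - r0) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def coordinate_rmsd(a, b) -> float:
    """Raw (unsuperposed) RMSD between two equal-length coordinate arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def backbone_coordinates(assembly: Assembly) -> np.ndarray:
    """Backbone (N, CA, C, O) coordinates of every protein residue, in
    chain order, residue order, fixed atom-label order."""
    coords = []
    for chain in assembly:
        if chain.polymer_type != "protein":
            continue
        for res in chain:
            for atom in res.backbone_atoms():
                coords.append(atom.coords)
    return np.array(coords, dtype=float)


def backbone_rmsd(a: Assembly, b: Assembly, superposed: bool = True) -> RmsdReport:
    """Backbone RMSD between two assemblies with positional correspondence.

    Atoms are paired in chain order, residue order, label order
    (N, CA, C, O).  With ``superposed`` the RMSD after optimal rigid
    superposition is reported, otherwise the raw value.
    """
    counts_a = [len(c) for c in a if c.polymer_type == "protein"]
    counts_b = [len(c) for c in b if c.polymer_type == "protein"]
    if counts_a != counts_b:
        raise ValueError(
            f"residue-count mismatch between assemblies: "
            f"per-chain counts {counts_a} vs {counts_b}")
    ca = backbone_coordinates(a)
    cb = backbone_coordinates(b)
    n_res = sum(counts_a)
    if superposed:
        rmsd = superpose(ca, cb).rmsd
    else:
        rmsd = coordinate_rmsd(ca, cb)
    r100 = rmsd100(rmsd, n_res) if n_res >= RMSD100_MIN_RESIDUES else None
    return RmsdReport(rmsd=rmsd, n_atoms=len(ca), rmsd100=r100)


def rmsd100(rmsd: float, n_residues: int) -> float:
    """Length-normalized RMSD: RMSD / (1 + ln √(N/100)).

    Defined here for N ≥ 20; the denominator changes sign near
    N = 100/e² ≈ 13.5 where the normalization loses meaning.
    """
    if n_residues < RMSD100_MIN_RESIDUES:
        raise ValueError(
            f"rmsd100 requires n_residues >= {RMSD100_MIN_RESIDUES} "
            f"(the normalization denominator vanishes near N = 13.5); "
            f"got {n_residues}")
    return float(rmsd / (1.0 + np.log(np.sqrt(n_residues / 100.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about the p2–p3 axis, degrees in (−180, 180].

    IUPAC sign convention: cis = 0, trans = 180.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < 1e-10:
        raise ValueError("degenerate geometry: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: three consecutive points collinear")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    angle = float(np.degrees(np.arctan2(-y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def fit_axis(points) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line through a point cloud.

    Returns (centroid, unit direction), the direction being the principal
    axis of the centered points.  The direction's sign is fixed so that it
    has a non-negative projection on the first-to-last point vector.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("axis fit needs >= 3 points")
    centroid = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - centroid)
    direction = Vt[0]
    span = pts[-1] - pts[0]
    if direction @ span < 0:
        direction = -direction
    return centroid, direction / np.linalg.norm(direction)
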