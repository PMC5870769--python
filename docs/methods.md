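# Methods

## Structure model

Structures are held in a four-level hierarchy — Assembly → Polymer →
Residue → Atom — navigable in both directions, with coordinates in Å
(float64).  Protein builders emit glycine residues carrying the four
backbone atoms N, CA, C, O; "backbone RMSD" throughout means these
four atoms, paired positionally (chain order, residue order, fixed
label order).  The smoothed Cα trace of a chain (its *primitive*) is a
centered running mean of width 3, truncated to width 2 at the ends so
the trace keeps one point per residue.  Width 3 is the smallest
symmetric window; note that it only attenuates, not cancels, the Cα
helix radius (for an α-helix the residual radius is
(1 + 2 cos Ω)/3 ≈ 0.22 of the original, Ω = twist per residue).

## Helix classes and the two construction routes

A helix class (α, π, polyproline II) is *defined* by canonical
backbone torsions:

| class | φ (°)  | ψ (°)  | derived rise (Å) | Cα radius (Å) | res/turn | handedness |
|-------|--------|--------|------------------|---------------|----------|------------|
| α     | −57.8  | −47.0  | 1.480            | 2.285         | 3.609    | right      |
| π     | −57.0  | −70.0  | 0.958            | 2.711         | 4.222    | right      |
| PPII  | −75.0  | 145.0  | 3.066            | 1.293         | 3.006    | left       |

The cylinder constants are **derived, not declared**: a reference
helix is built from the canonical torsions by sequential
internal-to-Cartesian placement (each atom placed from the previous
three by bond length, bond angle, torsion), and its per-residue screw
transform is extracted by superposing residues i onto i+1.  The screw
axis, twist and rise give the cylinder constants, and each backbone
atom type's cylinder radius, phase offset and axial offset relative to
Cα give the placement rule for the path-following builders.  Deriving
rather than hand-declaring these constants makes the torsion route and
the path route agree to machine precision and guarantees peptide-bond
continuity (|C(i)−N(i+1)| = 1.330 Å exactly on a straight axis); we
found that plausible hand-declared constants (e.g. a 1.0 Å PPII
radius) break continuity by >0.15 Å.

Default bond geometry: N–CA 1.47, CA–C 1.53, C–N 1.33, C=O 1.24 Å;
angles N–CA–C 110°, CA–C–N 114°, C–N–CA 121°, CA–C–O 121°, carbonyl O
in the peptide plane.  Torsions follow the IUPAC sign convention
(validated against an independent library implementation).

## Supercoiled helices and coiled coils

`build_helical_helix` maps the straight-helix cylinder onto a
superhelical path of radius r₀ and pitch P about the z-axis.  Residue
i sits at arc length i·(rise per residue) along the path; each atom is
displaced from the path point in the local frame (n̂ toward the
superhelix axis, b̂ = t̂ × n̂).  Because this frame itself rotates about
the tangent as the path advances (at the path's torsion,
τ = k/λ² with k = ±2π/P and λ the arc length per unit z), the applied
minor-helix phase is corrected by −τ·s; this is what preserves local
helical geometry on the curved path.  In the infinite-pitch limit the
construction reduces to the straight helix (RMSD < 1e-8 Å at
P = 10⁶ Å), and C–N continuity holds within ±0.005 Å at coiled-coil
curvatures.

The interface angle φCα rotates the minor helix about its own path
tangent; **zero means the first residue's Cα points toward the
superhelix axis**.  This zero reference (and the z-shift origin at
z = 0) is a convention of this package; fitted φCα and z-shift values
are therefore not comparable across implementations — only RMSDs are.

A coiled coil is n such chains with chain k phase-shifted by k·360°/n,
giving exact Cₙ symmetry, then individually rotated (chain_rotation,
an extra spin about the chain's own path) and z-shifted.  Superhelix
handedness defaults to left for α coiled coils and right for
tropocollagen (collagen = the same specification with PPII strands and
three chains; staggered per-chain z-shifts create the leading/lagging
strands).  An antiparallel chain is built axis-negated via a proper
rotation (chirality preserved); only parallel topologies are exercised
by the validation suite.  Mirror symmetry between left- and
right-handed superhelices is exact only when the minor helix class is
mirrored too (reflection flips both chiralities).

## Helix pairs and solenoids

The solenoid repeat unit is two α-helices placed about a reference
(z) axis: helix j is centred at the origin, spun by its φCα, tilted
in-plane (splay, about y), rotated about the radial x direction
(off-plane rotation; 180° points it antiparallel to the reference
axis), then translated to ±axis_distance along x and z_shift along z
(the two helices sit on opposite sides of the axis).

`build_solenoid` first canonicalizes the unit — centroid at the
origin, principal axes aligned to (z, y, x) with deterministic sign
fixing — so that rigidly transformed copies of the same unit produce
identical solenoids.  The unit is then rotated by unit_rotation about
the radial direction, placed at the solenoid radius, and replicated by
the screw transform (twist per repeat about z, rise per repeat along
z, sign by handedness).

## DNA duplexes

B-form defaults: rise 3.38 Å and twist 34.3° per base pair.  The
base-pair template is **synthetic**: an idealized planar arrangement,
constructed geometrically in code, carrying C1′, the backbone trace
(P, O5′, C5′, C4′, C3′, O3′) and a base ring trace (9 atoms for
purines, 6 for pyrimidines).  Duplex-level geometry (rise, twist,
antiparallel reverse-complement strands, pairing by an in-plane dyad)
is exact; within-base geometry is approximate and not intended for
atomistic analysis.

## Superposition and RMSD₁₀₀

Superposition minimizes RMSD over the 1:1 atom correspondence by the
Kabsch/SVD method with reflection correction (det = +1 enforced) —
numerically equivalent, for the minimized RMSD, to the classic
least-squares algorithms.  No alignment search is performed: residue
correspondence is positional, which is appropriate because models are
rebuilt at the target's exact chain and residue counts.

RMSD₁₀₀ = RMSD / (1 + ln √(N/100)) normalizes to a 100-residue
reference length.  The denominator vanishes at N = 100/e² ≈ 13.5, so
the function's domain is cut at N ≥ 20 (experiments comparing RMSD₁₀₀
across structures should use comfortably longer chains, e.g. ≥ 45
residues).

## Optimization

DE/rand/1/bin: the parent population is sampled uniformly in the
search box from a single seed; each generation every member receives a
mutant a + F·(b − c) from three distinct other members, binomial
crossover at rate CR with one forced dimension, clipping to bounds,
greedy selection.  Defaults F = 0.75, CR = 0.8 (standard DE values,
exposed in `OptimizerConfig`).  Integer dimensions are rounded at
evaluation time.  Total model evaluations are population ×
(generations + 1) — the parent generation plus one candidate
population per generation — giving 1020, 1530, 2550 and 4040 for the
four standard protocols (20×50, 30×50, 50×50, 40×100).  Runs are
bit-reproducible for a given seed; in the two-stage solenoid fit the
second stage derives its seed as seed + 1 unless configured
explicitly.

Structure fitting minimizes the superposed backbone RMSD between the
built model and the target, with chain/residue counts taken from the
target and validated before optimization.  Hydroxyproline residues in
targets are converted to proline (backbone-identical) before fitting.
Packaged search ranges: coiled-coil radius by oligomer state (dimer
3.5–5.5, trimer 5.0–7.0, tetramer 5.5–8.5, pentamer 6.5–9.5 Å), pitch
50–350 Å, interface angle ±20°; collagen radius 1.5–5.5 Å, pitch
25–105 Å, unrestricted interface angle, per-chain z-shift 0.0–6.2 Å
and rotation ±30°; repeat unit axis distance 0.0–6.0 Å, z-shift ±6 Å,
unrestricted spin, splay −45° to 5°, off-plane 90–270°; solenoid
radius 25–45 Å, rise 2–18 Å, unrestricted twist and unit rotation.
The collagen protocol keeps both a global interface angle and
per-chain rotations; the resulting exact degeneracies (a uniform
rotation offset, a uniform z-shift) are harmless because the fitness
is superposition-invariant.

The objective is evaluated through an array-only code path (no atom
objects) that is bit-identical to the public builders; evaluations
could be distributed across workers without changing results, since
selection depends only on each member's own score.

## Synthetic validation targets

The reference conditions fitted by the validation suite and
`scripts/acceptance.py` are self-built structures with ground-truth
parameters inside, but off-centre of, the packaged ranges: a trimer
(r 6.5 Å, P 150 Å, φCα 10°, 3×28 residues), a collagen triple helix
(r 3.0 Å, P 85 Å, φCα 40°, z-shifts 0.8/2.9/5.0 Å, rotations
−10/5/20°, 3×30 residues) and a 5-repeat solenoid (radius 32 Å, rise
10 Å, twist 12°, 2×10-residue unit).  The optional Gaussian coordinate
noise of the fixture generator emulates coordinate-level disagreement
between an idealized model and a real structure (unsuperposed RMSD
≈ σ√3); it does not emulate sequence-dependent geometry, supercoil
bending, or irregular termini, so noiseless/noisy recovery results
bound what the method can do on ideal data, not on crystal structures.
Problem sizes (≈ 100 residues, ≤ 4040 evaluations per fit) keep a full
validation run around a minute on one CPU while using the standard
budgets above.

## Known limitations

* Backbone/glycine models only: no side chains, β-structures, loops
  between segments, or force-field scoring; fitness functions other
  than RMSD are out of scope.
* Fitted parameter *values* are convention-dependent (φCα zero,
  z-shift origin, helix-pair frame); only RMSDs transfer across
  implementations.
* The solenoid fit assumes repeats map to equal blocks of consecutive
  chains; single-chain repeat proteins must be split into repeat
  chains beforehand.
* PDB I/O covers the coordinate section of the v3.3 fixed-column
  format (first model, altloc blank/A); no mmCIF.
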