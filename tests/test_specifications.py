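"""Parametric builders: helices, coiled coils, collagen, solenoids, DNA."""

import numpy as np
import pytest

from helixforge.core import rotation_matrix
from helixforge.geometry import (backbone_coordinates, backbone_rmsd,
                                 coordinate_rmsd, fit_axis, superpose)
from helixforge.specifications import (ALPHA, PI, PPII, BondGeometry,
                                       CrickParams, DnaDuplexParams,
                                       HelixClass, HelixPairParams,
                                       SolenoidParams, TorsionTriple,
                                       backbone_torsions, build_coiled_coil,
                                       build_dna_duplex, build_helical_helix,
                                       build_helix, build_helix_pair,
                                       build_solenoid, build_ta_polypeptide,
                                       build_tropocollagen)

BB = ("N", "CA", "C", "O")


def chain_bb(chain):
    return np.array([r[l].coords for r in chain.residues for l in BB])


def peptide_cn_lengths(assembly_or_chain):
    from helixforge.core import Polymer
    chains = ([assembly_or_chain] if isinstance(assembly_or_chain, Polymer)
              else list(assembly_or_chain))
    out = []
    for ch in chains:
        for i in range(len(ch) - 1):
            out.append(np.linalg.norm(ch[i + 1]["N"].coords - ch[i]["C"].coords))
    return np.array(out)


class TestBuildHelix:
    def test_counts(self):
        h = build_helix(ALPHA, 10)
        assert len(h) == 10
        assert sum(len(r) for r in h) == 40
        assert all(r.is_backbone_complete for r in h)
        assert all(r.mol_code == "GLY" for r in h)

    def test_axial_extent_matches_rise(self):
        n = 18
        h = build_helix(ALPHA, n)
        z = h.ca_coordinates()[:, 2]
        assert z[-1] - z[0] == pytest.approx(
            (n - 1) * ALPHA.rise_per_residue, abs=0.05)

    def test_interior_torsions_are_canonical(self, alpha_helix):
        torsions = backbone_torsions(alpha_helix)[2:-2]
        for t in torsions:
            assert t["phi"] == pytest.approx(-57.8, abs=3.0)
            assert t["psi"] == pytest.approx(-47.0, abs=3.0)

    def test_arbitrary_axis(self):
        start, end = np.array([1.0, 2.0, 3.0]), np.array([4.0, 2.0, 3.0])
        h = build_helix(ALPHA, 12, start=start, end=end)
        _, direction = fit_axis(h.ca_coordinates())
        # least-squares axis of a non-integer number of turns has small
        # end effects; a couple of degrees of slack suffices here
        assert abs(direction @ [1, 0, 0]) > np.cos(np.radians(3.0))

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_helix(ALPHA, 1)
        with pytest.raises(ValueError, match="coincide"):
            build_helix(ALPHA, 5, start=(0, 0, 0), end=(0, 0, 0))


class TestTorsionBuilder:
    def test_torsions_round_trip(self):
        triples = [TorsionTriple(-57.8, -47.0, 180.0)] * 15
        poly = build_ta_polypeptide(triples)
        measured = backbone_torsions(poly)
        for i, t in enumerate(measured):
            if t["phi"] is not None:
                assert t["phi"] == pytest.approx(-57.8, abs=1e-6)
            if t["psi"] is not None:
                assert t["psi"] == pytest.approx(-47.0, abs=1e-6)
            if t["omega"] is not None:
                assert abs(t["omega"]) == pytest.approx(180.0, abs=1e-6)

    def test_cross_route_agreement_with_path_builder(self):
        ta = build_ta_polypeptide([ALPHA.canonical_torsions] * 15)
        h = build_helix(ALPHA, 15)
        assert superpose(chain_bb(ta), chain_bb(h)).rmsd < 0.6

    def test_trans_peptide_planes(self):
        poly = build_ta_polypeptide([TorsionTriple(-57.8, -47.0, 180.0)] * 8)
        res = poly.residues
        for i in range(len(res) - 1):
            quartet = np.array([res[i]["CA"].coords, res[i]["C"].coords,
                                res[i + 1]["N"].coords, res[i + 1]["CA"].coords])
            centroid = quartet.mean(axis=0)
            _, s, _ = np.linalg.svd(quartet - centroid)
            assert s[-1] < 1e-6  # coplanar

    def test_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_ta_polypeptide([TorsionTriple(-60, -40)])
        with pytest.raises(ValueError, match="bond length"):
            build_ta_polypeptide([TorsionTriple(-60, -40)] * 3,
                                 BondGeometry(n_ca=2.5))


class TestHelicalHelix:
    def test_infinite_pitch_reduces_to_straight_helix(self):
        hh = build_helical_helix(ALPHA, 20, r0=5.0, pitch=1e6)
        h = build_helix(ALPHA, 20)
        assert superpose(chain_bb(hh), chain_bb(h)).rmsd < 0.05

    def test_ca_radius_bounded_by_minor_radius(self):
        r0 = 5.0
        hh = build_helical_helix(ALPHA, 30, r0=r0, pitch=120.0)
        d = np.linalg.norm(hh.ca_coordinates()[:, :2], axis=1)
        bound = ALPHA.helix_radius + 0.2
        assert np.all(d > r0 - bound) and np.all(d < r0 + bound)

    def test_mirror_image_handedness(self):
        mirror_alpha = HelixClass("alpha_mirror", TorsionTriple(57.8, 47.0))
        left = build_helical_helix(ALPHA, 20, r0=5.0, pitch=120.0,
                                   handedness="left")
        right = build_helical_helix(mirror_alpha, 20, r0=5.0, pitch=120.0,
                                    handedness="right")
        reflected = chain_bb(left) * np.array([1.0, -1.0, 1.0])
        assert coordinate_rmsd(reflected, chain_bb(right)) < 1e-6

    def test_local_geometry_preserved(self):
        hh = build_helical_helix(ALPHA, 28, r0=6.0, pitch=150.0)
        cn = peptide_cn_lengths(hh)
        assert np.all(np.abs(cn - 1.33) < 0.1)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="positive"):
            build_helical_helix(ALPHA, 10, r0=-1.0, pitch=100.0)
        with pytest.raises(ValueError, match="positive"):
            build_helical_helix(ALPHA, 10, r0=5.0, pitch=0.0)


class TestCoiledCoil:
    def test_counts(self):
        cc = build_coiled_coil(CrickParams(
            n_chains=3, superhelix_radius=6.0, pitch=150.0,
            interface_angle=0.0, n_residues=28))
        assert len(cc) == 3
        assert cc.n_atoms() == 3 * 28 * 4

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_cn_symmetry(self, n):
        cc = build_coiled_coil(CrickParams(
            n_chains=n, superhelix_radius=5.0 + 0.5 * n, pitch=160.0,
            interface_angle=8.0, n_residues=20))
        R = rotation_matrix((0, 0, 1), 360.0 / n)
        rotated = chain_bb(cc[0]) @ R.T
        assert coordinate_rmsd(rotated, chain_bb(cc[1])) < 1e-6

    def test_superhelix_radius_recovered(self):
        r = 6.0
        cc = build_coiled_coil(CrickParams(
            n_chains=3, superhelix_radius=r, pitch=150.0, n_residues=28))
        mean_d = np.mean([
            np.linalg.norm(ch.ca_coordinates()[:, :2], axis=1).mean()
            for ch in cc])
        assert mean_d == pytest.approx(r, abs=0.3)

    def test_peptide_continuity(self):
        cc = build_coiled_coil(CrickParams(
            n_chains=2, superhelix_radius=4.5, pitch=120.0, n_residues=24))
        assert np.all(np.abs(peptide_cn_lengths(cc) - 1.33) < 0.1)

    def test_determinism(self):
        p = CrickParams(n_chains=3, superhelix_radius=6.2, pitch=140.0,
                        interface_angle=3.0, n_residues=25)
        a = build_coiled_coil(p).coordinates()
        b = build_coiled_coil(p).coordinates()
        assert np.array_equal(a, b)

    def test_parameter_smoothness(self):
        base = dict(n_chains=3, superhelix_radius=6.0, pitch=150.0,
                    interface_angle=5.0, n_residues=24)
        ref = backbone_coordinates(build_coiled_coil(CrickParams(**base)))
        for name in ("superhelix_radius", "pitch", "interface_angle"):
            rmsds = []
            for eps in (1.002, 1.005, 1.01):
                params = dict(base)
                params[name] = base[name] * eps
                pert = backbone_coordinates(
                    build_coiled_coil(CrickParams(**params)))
                rmsds.append(superpose(pert, ref).rmsd)
            assert rmsds[0] < rmsds[1] < rmsds[2]
            assert rmsds[2] < 2.0  # 1% perturbations stay small

    def test_validation(self):
        with pytest.raises(ValueError, match="superhelix_radius"):
            build_coiled_coil(CrickParams(n_chains=2, superhelix_radius=-1))
        with pytest.raises(ValueError, match="n_chains"):
            build_coiled_coil(CrickParams(n_chains=1))


class TestTropocollagen:
    def test_counts(self):
        tc = build_tropocollagen(CrickParams(
            n_chains=3, superhelix_radius=3.0, pitch=85.0, n_residues=30,
            superhelix_handedness="right"))
        assert len(tc) == 3
        assert tc.n_atoms() == 360

    def test_z_shift_stagger_ordering(self):
        tc = build_tropocollagen(CrickParams(
            n_chains=3, superhelix_radius=3.0, pitch=85.0, n_residues=30,
            z_shift=(0.0, 2.1, 4.2), superhelix_handedness="right"))
        centroids = [ch.ca_coordinates()[:, 2].mean() for ch in tc]
        assert centroids[0] < centroids[1] < centroids[2]
        assert centroids[1] - centroids[0] == pytest.approx(2.1, abs=1e-9)
        assert centroids[2] - centroids[1] == pytest.approx(2.1, abs=1e-9)

    def test_strand_torsions_are_ppii(self):
        tc = build_tropocollagen(CrickParams(
            n_chains=3, superhelix_radius=3.0, pitch=85.0, n_residues=30,
            superhelix_handedness="right"))
        want = PPII.canonical_torsions
        for strand in tc:
            for t in backbone_torsions(strand)[2:-2]:
                assert t["phi"] == pytest.approx(want.phi, abs=5.0)
                assert t["psi"] == pytest.approx(want.psi, abs=5.0)

    def test_requires_three_chains(self):
        with pytest.raises(ValueError, match="3 chains"):
            build_tropocollagen(CrickParams(n_chains=2))


class TestHelixPair:
    def test_parallel_axes_at_twice_axis_distance(self):
        hp = build_helix_pair(HelixPairParams(
            axis_distance=(3.0, 3.0), helix_lengths=(12, 12)))
        c1, d1 = fit_axis(hp[0].ca_coordinates())
        c2, d2 = fit_axis(hp[1].ca_coordinates())
        assert abs(d1 @ d2) == pytest.approx(1.0, abs=1e-6)
        delta = c2 - c1
        assert np.linalg.norm(delta - (delta @ d1) * d1) == \
            pytest.approx(6.0, abs=0.2)

    def test_splay_changes_interaxis_angle(self):
        def angle(splay):
            hp = build_helix_pair(HelixPairParams(
                axis_distance=(3.0, 3.0), splay=(splay, 0.0),
                helix_lengths=(12, 12)))
            _, d1 = fit_axis(hp[0].ca_coordinates())
            _, d2 = fit_axis(hp[1].ca_coordinates())
            return np.degrees(np.arccos(np.clip(abs(d1 @ d2), -1, 1)))
        assert angle(10.0) - angle(0.0) == pytest.approx(10.0, abs=1.0)

    def test_sign_convention_mirrors_axis_placement(self):
        hp = build_helix_pair(HelixPairParams(
            axis_distance=(3.0, 3.0), helix_lengths=(10, 10)))
        c1, _ = fit_axis(hp[0].ca_coordinates())
        c2, _ = fit_axis(hp[1].ca_coordinates())
        # The two helices sit symmetrically across the reference (yz) plane
        # (fit_axis centroids carry ~0.02 Å of Cα-vs-backbone offset).
        assert c1[0] == pytest.approx(-c2[0], abs=0.05)
        assert c1[0] == pytest.approx(3.0, abs=0.1)

    def test_validation(self):
        with pytest.raises(ValueError, match="2-sequence"):
            build_helix_pair(HelixPairParams(axis_distance=(1, 2, 3)))


class TestSolenoid:
    @pytest.fixture
    def unit(self):
        return HelixPairParams(axis_distance=(3.0, 4.5), z_shift=(-1.0, 1.5),
                               phi_ca=(30.0, -60.0), splay=(-12.0, -4.0),
                               off_plane_rotation=(120.0, 240.0),
                               helix_lengths=(10, 10))

    def test_counts(self, unit):
        sol = build_solenoid(SolenoidParams(repeat_unit=unit, n_repeats=5,
                                            radius=32.0, rise_per_repeat=10.0,
                                            twist_per_repeat=12.0))
        assert len(sol) == 10
        assert sum(len(ch) for ch in sol) == 100

    def test_constant_screw_transform(self, unit):
        sol = build_solenoid(SolenoidParams(repeat_unit=unit, n_repeats=5,
                                            radius=32.0, rise_per_repeat=10.0,
                                            twist_per_repeat=12.0))
        def repeat_bb(i):
            return np.vstack([chain_bb(sol[2 * i]), chain_bb(sol[2 * i + 1])])
        results = [superpose(repeat_bb(i), repeat_bb(i + 1)) for i in range(4)]
        for sp in results:
            assert sp.rmsd < 1e-6
        for sp in results[1:]:
            assert np.allclose(sp.rotation, results[0].rotation, atol=1e-6)
            assert np.allclose(sp.translation, results[0].translation,
                               atol=1e-6)

    def test_zero_twist_is_pure_translation_stack(self, unit):
        h = 9.0
        sol = build_solenoid(SolenoidParams(repeat_unit=unit, n_repeats=4,
                                            radius=30.0, rise_per_repeat=h,
                                            twist_per_repeat=0.0))
        centroids = np.array([
            np.vstack([chain_bb(sol[2 * i]), chain_bb(sol[2 * i + 1])])
            .mean(axis=0) for i in range(4)])
        steps = np.diff(centroids, axis=0)
        assert np.allclose(steps[:, :2], 0.0, atol=1e-6)
        assert np.allclose(steps[:, 2], h, atol=1e-6)

    def test_pose_invariance_of_canonicalization(self, unit):
        from helixforge.core import rotate, translate
        from helixforge.specifications import build_helix_pair
        p = SolenoidParams(repeat_unit=build_helix_pair(unit), n_repeats=3,
                           radius=30.0, rise_per_repeat=8.0,
                           twist_per_repeat=15.0)
        a = build_solenoid(p).coordinates()
        moved = build_helix_pair(unit)
        rotate(moved, (1, 2, 3), 55.0, point=(5, -2, 1))
        translate(moved, (10.0, -4.0, 2.0))
        p2 = SolenoidParams(repeat_unit=moved, n_repeats=3, radius=30.0,
                            rise_per_repeat=8.0, twist_per_repeat=15.0)
        b = build_solenoid(p2).coordinates()
        assert np.allclose(a, b, atol=1e-6)

    def test_validation(self, unit):
        with pytest.raises(ValueError, match="n_repeats"):
            build_solenoid(SolenoidParams(repeat_unit=unit, n_repeats=1))


class TestDnaDuplex:
    def test_reverse_complement_strands(self):
        dna = build_dna_duplex(DnaDuplexParams("GATTACA"))
        assert len(dna) == 2
        assert [len(s) for s in dna] == [7, 7]
        assert "".join(r.mol_code[1] for r in dna[1]) == "TGTAATC"
        assert all(s.polymer_type == "nucleic" for s in dna)

    def test_axial_extent(self):
        p = DnaDuplexParams("ACGTACGTAC")
        dna = build_dna_duplex(p)
        pair_z = []
        for i, res in enumerate(dna[0]):
            partner = dna[1][len(dna[0]) - 1 - i]
            zs = [a.coords[2] for a in res] + [a.coords[2] for a in partner]
            pair_z.append(np.mean(zs))
        assert pair_z[-1] - pair_z[0] == pytest.approx(
            9 * p.rise_per_bp, abs=0.1)

    def test_full_turn_identity(self):
        dna = build_dna_duplex(DnaDuplexParams("A" * 11, twist_per_bp=36.0))
        def orientation(i):
            res = dna[0][i]
            v = res["C1'"].coords - res["C4'"].coords
            v[2] = 0.0
            return v / np.linalg.norm(v)
        assert np.allclose(orientation(10), orientation(0), atol=1e-6)

    def test_invalid_base_named(self):
        with pytest.raises(ValueError, match="position 3"):
            build_dna_duplex(DnaDuplexParams("GAXTACA"))


class TestClassConstants:
    def test_handedness(self):
        assert ALPHA.handedness == "right"
        assert PI.handedness == "right"
        assert PPII.handedness == "left"

    def test_ppii_continuity(self):
        # PPII is the continuity stress case: derived constants must keep
        # the peptide bond intact.
        h = build_helix(PPII, 15)
        assert np.all(np.abs(peptide_cn_lengths(h) - 1.33) < 0.1)
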