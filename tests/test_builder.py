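import math

import numpy as np
import pytest

from gvshell import builder, geometry, synth
from gvshell.structure_io import read_structure_file, write_structure_file

from conftest import pairwise_distances, total_arc_oracle


class TestLoadMonomer:
    def test_toy_monomer_is_valid(self, toy_template):
        assert toy_template.missing_landmarks() == []

    def test_round_trip_through_pdb(self, toy_template, tmp_path):
        path = tmp_path / "monomer.pdb"
        write_structure_file(toy_template.to_atom_array(), path)
        loaded = builder.load_monomer(path)
        assert loaded.n_atoms == toy_template.n_atoms
        np.testing.assert_allclose(loaded.coords, toy_template.coords, atol=1e-3)

    def test_missing_landmark_is_named(self, toy_template, tmp_path):
        keep = ~((toy_template.atom_names == "CA") & (toy_template.res_ids == 23))
        broken = builder.MonomerTemplate(
            atom_names=toy_template.atom_names[keep],
            res_ids=toy_template.res_ids[keep],
            elements=toy_template.elements[keep],
            coords=toy_template.coords[keep],
            occupancy=toy_template.occupancy[keep])
        path = tmp_path / "broken.pdb"
        write_structure_file(broken.to_atom_array(), path)
        with pytest.raises(builder.LandmarkError, match="CA 23"):
            builder.load_monomer(path)

    def test_unreadable_format(self, tmp_path):
        path = tmp_path / "monomer.xyz"
        path.write_text("nonsense")
        with pytest.raises(ValueError):
            builder.load_monomer(path)


class TestAlignCurveToPivot:
    def test_already_seated_is_identity(self, toy_template, default_spec):
        aligned, report = builder.align_curve_to_pivot(toy_template, default_spec)
        assert report["z_rotation"] == pytest.approx(0.0, abs=1e-9)
        assert report["z_shift"] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(aligned.coords, toy_template.coords, atol=1e-9)

    def test_azimuthal_offset(self, toy_template, default_spec):
        from scipy.spatial.transform import Rotation

        rotated = toy_template.with_coords(
            Rotation.from_euler("z", 30, degrees=True).apply(toy_template.coords))
        _, report = builder.align_curve_to_pivot(rotated, default_spec)
        assert report["z_rotation"] == pytest.approx(-30.0, abs=1e-9)

    def test_z_offset(self, toy_template, default_spec):
        shifted = toy_template.with_coords(toy_template.coords + [0, 0, 5.0])
        aligned, report = builder.align_curve_to_pivot(shifted, default_spec)
        assert report["z_shift"] == pytest.approx(-5.0, abs=1e-9)
        np.testing.assert_allclose(aligned.pivot, [178.4, 0, 0], atol=1e-9)

    def test_radial_mismatch_rejected_without_shift(self, toy_template):
        spec = geometry.VesicleSpec(r_max=200.0)
        with pytest.raises(ValueError, match="radius"):
            builder.align_curve_to_pivot(toy_template, spec, allow_radial_shift=False)


class TestGeneratePlacements:
    def test_default_count(self, default_spec):
        ts = builder.generate_placements(default_spec)
        assert len(ts) == 865

    def test_count_from_arc_length_oracle(self, default_spec):
        total = total_arc_oracle(default_spec)
        expected = math.floor(total / default_spec.spacing) - default_spec.n_omit_tip
        assert len(builder.generate_placements(default_spec)) == expected

    def test_cone_only(self):
        spec = geometry.VesicleSpec(t_cyl=0.0, n_omit_tip=0)
        ts = builder.generate_placements(spec)
        assert len(ts) > 0
        assert np.all(ts >= 0)

    def test_exact_divisibility(self):
        turn = math.hypot(2 * math.pi * 178.4, 48.8)
        spec = geometry.VesicleSpec(t_cyl=1.0, spacing=turn / 10.0, n_omit_tip=0)
        ts = builder.generate_placements(spec)
        in_cyl = ts[ts < 1.0 - 1e-9]
        assert len(in_cyl) == 10
        np.testing.assert_allclose(in_cyl, np.arange(10) / 10.0, atol=1e-9)

    def test_spacing_separations(self, default_spec):
        ts = builder.generate_placements(default_spec)
        for k in (0, 1, 400, len(ts) - 2):
            sep = geometry.arc_length(default_spec, ts[k], ts[k + 1])
            assert sep == pytest.approx(default_spec.spacing, abs=1e-6)

    def test_oversized_spacing_rejected(self):
        spec = geometry.VesicleSpec(r_max=10.0, t_cyl=0.0, spacing=1e5)
        with pytest.raises(ValueError, match="spacing"):
            builder.generate_placements(spec)

    @pytest.mark.parametrize("r_max,alpha,t_cyl", [
        (178.4, 25.0, 5.0), (100.0, 25.0, 3.0), (178.4, 40.0, 2.0), (250.0, 25.0, 1.0),
    ])
    def test_count_scaling_matches_oracle(self, r_max, alpha, t_cyl):
        spec = geometry.VesicleSpec(r_max=r_max, cone_angle_alpha=alpha,
                                    t_cyl=t_cyl, n_omit_tip=0)
        total = total_arc_oracle(spec)
        assert len(builder.generate_placements(spec)) == math.floor(total / spec.spacing)


class TestLocalFrame:
    def test_cylinder_tangent_z_component(self, default_spec):
        q, _, at_tip = builder.local_frame(2.0, default_spec)
        tangent = q[:, 2]
        expected = 48.8 / math.hypot(2 * math.pi * 178.4, 48.8)
        assert tangent[2] == pytest.approx(expected, rel=1e-9)
        assert not at_tip

    def test_phase_convention(self, default_spec):
        q, origin, _ = builder.local_frame(0.0, default_spec)
        np.testing.assert_allclose(q[:, 0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(origin, [178.4, 0, 0], atol=1e-12)

    def test_orthonormal_right_handed(self, default_spec):
        for t in (0.0, 3.3, 7.0, 12.0):
            q, _, _ = builder.local_frame(t, default_spec)
            np.testing.assert_allclose(q.T @ q, np.eye(3), atol=1e-9)
            assert np.linalg.det(q) == pytest.approx(1.0, rel=1e-9)

    def test_helical_symmetry_between_turns(self, default_spec):
        from scipy.spatial.transform import Rotation

        # one full turn maps the frame onto itself with a pitch translation
        q1, p1, _ = builder.local_frame(1.0, default_spec)
        q2, p2, _ = builder.local_frame(2.0, default_spec)
        np.testing.assert_allclose(q2, q1, atol=1e-9)
        np.testing.assert_allclose(p2 - p1, [0, 0, 48.8], atol=1e-9)
        # one subunit step is a screw by the helical twist about z
        ut = 92.93
        q3, _, _ = builder.local_frame(1.0 + 1.0 / ut, default_spec)
        rotvec = Rotation.from_matrix(q3 @ q1.T).as_rotvec(degrees=True)
        np.testing.assert_allclose(rotvec, [0, 0, -360.0 / ut], atol=1e-6)

    def test_tip_is_flagged(self, default_spec):
        _, _, at_tip = builder.local_frame(default_spec.t_end, default_spec)
        assert at_tip


class TestApplyCorrection:
    @pytest.mark.parametrize("which", builder.CORRECTION_NAMES)
    def test_zero_angle_is_identity(self, toy_template, which):
        out = builder.apply_correction(toy_template, which, 0.0)
        np.testing.assert_array_equal(out.coords, toy_template.coords)

    @pytest.mark.parametrize("which", builder.CORRECTION_NAMES)
    def test_inverse_rotation(self, toy_template, which):
        fwd = builder.apply_correction(toy_template, which, 17.0)
        back = builder.apply_correction(fwd, which, -17.0)
        np.testing.assert_allclose(back.coords, toy_template.coords, atol=1e-9)

    @pytest.mark.parametrize("which", ["helixangle", "monomer_tilt"])
    def test_whole_monomer_rigidity(self, toy_template, which):
        out = builder.apply_correction(toy_template, which, 25.0)
        np.testing.assert_allclose(pairwise_distances(out.coords),
                                   pairwise_distances(toy_template.coords),
                                   atol=1e-9)

    def test_monomer_tilt_fixes_o36(self, toy_template):
        out = builder.apply_correction(toy_template, "monomer_tilt", 25.0)
        np.testing.assert_allclose(out.atom_coord("O", 36),
                                   toy_template.atom_coord("O", 36), atol=1e-9)

    def test_helixangle_fixes_pivot(self, toy_template):
        out = builder.apply_correction(toy_template, "helixangle", 10.0)
        np.testing.assert_allclose(out.pivot, toy_template.pivot, atol=1e-9)

    def test_beta_tilt_moves_only_hairpin(self, toy_template):
        out = builder.apply_correction(toy_template, "beta_tilt", 15.0)
        moved = np.any(np.abs(out.coords - toy_template.coords) > 1e-12, axis=1)
        in_range = (toy_template.res_ids >= 23) & (toy_template.res_ids <= 49)
        assert not np.any(moved & ~in_range)
        # hinge endpoints stay on the axis
        np.testing.assert_allclose(out.atom_coord("CA", 23),
                                   toy_template.atom_coord("CA", 23), atol=1e-9)
        np.testing.assert_allclose(out.atom_coord("CA", 49),
                                   toy_template.atom_coord("CA", 49), atol=1e-9)

    def test_nterm_tilt_moves_only_arm(self, toy_template):
        out = builder.apply_correction(toy_template, "nterm_tilt", 15.0)
        moved = np.any(np.abs(out.coords - toy_template.coords) > 1e-12, axis=1)
        in_range = (toy_template.res_ids >= 2) & (toy_template.res_ids <= 23)
        assert not np.any(moved & ~in_range)

    def test_degenerate_plane_rejected(self, toy_template):
        coords = toy_template.coords.copy()
        mask = (toy_template.atom_names == "CB")
        coords[mask, :2] = 0.0  # collapse CB atoms onto a line
        flat = toy_template.with_coords(coords)
        with pytest.raises(ValueError, match="collinear"):
            builder.apply_correction(flat, "monomer_tilt", 5.0)

    def test_unknown_name_rejected(self, toy_template):
        with pytest.raises(ValueError):
            builder.apply_correction(toy_template, "sideways", 5.0)


class TestBuildHalfShell:
    def test_monomer_count(self, half_shell):
        assert half_shell.n_monomers == 865

    def test_single_placement_is_rigid_copy(self, toy_template):
        spec = geometry.VesicleSpec(r_max=30.0, t_cyl=0.0, spacing=150.0,
                                    n_omit_tip=0)
        model = builder.build_half_shell(toy_template, spec,
                                         builder.CorrectionSchedule.zero())
        assert model.n_monomers == 1
        np.testing.assert_allclose(
            pairwise_distances(model.monomer_coords(model.placements[0])),
            pairwise_distances(toy_template.coords), atol=1e-9)

    def test_pivot_spacing_invariant(self, half_shell, default_spec):
        ts = [p.t for p in half_shell.placements]
        for k in (10, 500, 860):
            sep = geometry.arc_length(default_spec, ts[k], ts[k + 1])
            assert sep == pytest.approx(default_spec.spacing, abs=1e-6)

    def test_chord_never_exceeds_arc(self, half_shell, default_spec):
        pivots = half_shell.pivot_positions()
        chords = np.linalg.norm(np.diff(pivots, axis=0), axis=1)
        assert np.all(chords <= default_spec.spacing + 1e-9)

    def test_corrections_zero_in_cylinder(self, half_shell, default_spec):
        for p in half_shell.placements:
            if p.t < default_spec.t_cyl:
                assert all(v == 0.0 for v in p.corrections.values())

    def test_helixangle_correction_is_analytic(self, half_shell, default_spec):
        ref = math.degrees(math.atan2(default_spec.pitch,
                                      2 * math.pi * default_spec.r_max))
        for p in half_shell.placements[-10:]:
            expected = geometry.curve_point(p.t, default_spec).local_helix_angle - ref
            assert p.corrections["helixangle"] == pytest.approx(expected, abs=1e-9)

    def test_equivalence_with_helical_expand(self, toy_template):
        ut = 92.93
        s = geometry.spacing_on_helix(178.4, 48.8, ut)
        spec = geometry.VesicleSpec(spacing=s, n_omit_tip=0)
        model = builder.build_half_shell(toy_template, spec,
                                         builder.CorrectionSchedule.zero())
        n = 20
        expanded = builder.helical_expand(toy_template, 48.8 / ut, -360.0 / ut, n)
        built = np.concatenate([model.monomer_coords(p) for p in model.placements[:n]])
        assert np.abs(built - expanded.all_coords()).max() < 1e-6


class TestDuplicateD1:
    def test_total_count(self, full_shell):
        assert full_shell.n_monomers == 1730

    def test_duplicating_twice_rejected(self, full_shell):
        with pytest.raises(ValueError):
            builder.duplicate_d1(full_shell)

    def test_d1_symmetry_rmsd(self, full_shell):
        from scipy.spatial import cKDTree

        coords = full_shell.all_coords()
        rotated = coords @ np.diag([1.0, -1.0, -1.0]).T
        d, _ = cKDTree(coords).query(rotated)
        assert d.max() < 1e-6

    def test_single_monomer_half(self, toy_template):
        spec = geometry.VesicleSpec(r_max=30.0, t_cyl=0.0, spacing=150.0,
                                    n_omit_tip=0)
        half = builder.build_half_shell(toy_template, spec,
                                        builder.CorrectionSchedule.zero())
        full = builder.duplicate_d1(half)
        assert full.n_monomers == 2
        pivots = full.pivot_positions()
        np.testing.assert_allclose(pivots[1], pivots[0] * [1, -1, -1], atol=1e-9)

    def test_chain_prefix(self, full_shell):
        chains = [p.chain_id for p in full_shell.placements]
        assert chains[0] == "A"
        assert chains[865] == "xA"
        assert len(set(chains)) == 1730


class TestHelicalExpand:
    def test_identity_for_single_copy(self, toy_template):
        model = builder.helical_expand(toy_template, 0.525, -3.874, 1)
        np.testing.assert_allclose(model.all_coords(), toy_template.coords, atol=1e-12)

    def test_fifteen_subunit_segment(self, toy_template):
        model = builder.helical_expand(toy_template, 0.525, -3.874, 15)
        assert model.n_monomers == 15
        assert [p.chain_id for p in model.placements[:3]] == ["A", "B", "C"]

    def test_accumulated_screw_closes_one_turn(self, toy_template):
        ut = 92.93
        model = builder.helical_expand(toy_template, 48.8 / ut, -360.0 / ut, 94)
        p = model.placements[93]  # index ut rounds to 93 applications
        from scipy.spatial.transform import Rotation

        angle = Rotation.from_matrix(p.rotation).as_rotvec(degrees=True)[2]
        assert angle == pytest.approx(-360.0 * 93 / ut + 360.0, abs=1e-9)
        assert p.translation[2] == pytest.approx(48.8 * 93 / ut, rel=1e-9)

    def test_invalid_n(self, toy_template):
        with pytest.raises(ValueError):
            builder.helical_expand(toy_template, 0.5, -3.9, 0)


class TestClashReport:
    def test_two_overlapping_copies(self, toy_template):
        placements = [
            builder.Placement(t=0.0, rotation=np.eye(3), translation=np.zeros(3),
                              chain_id="A"),
            builder.Placement(t=0.0, rotation=np.eye(3), translation=np.array([1.0, 0, 0]),
                              chain_id="B"),
        ]
        model = builder.ShellModel(placements=placements, template=toy_template)
        report = builder.clash_report(model, cutoff=2.0)
        assert len(report) > 0
        assert all(entry[4] < 2.0 for entry in report)

    def test_matches_brute_force(self, toy_template):
        spec = geometry.VesicleSpec(spacing=40.0, t_cyl=1.0, n_omit_tip=0)
        model = builder.build_half_shell(toy_template, spec,
                                         builder.CorrectionSchedule.zero())
        model = builder.ShellModel(placements=model.placements[:8],
                                   template=toy_template, spec=spec)
        cutoff = 5.0
        report = builder.clash_report(model, cutoff=cutoff, atom_names=None)
        coords = model.all_coords()
        n_per = toy_template.n_atoms
        chains = np.repeat(np.arange(8), n_per)
        diff = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        brute = np.sum((diff < cutoff) & (chains[:, None] != chains[None])) // 2
        assert len(report) == brute

    def test_empty_model(self, toy_template):
        model = builder.ShellModel(placements=[], template=toy_template)
        assert builder.clash_report(model) == []

    def test_full_model_clashes_near_tip(self, full_shell, default_spec):
        report = builder.clash_report(full_shell, cutoff=2.0)
        tip_chains = {p.chain_id for p in full_shell.placements
                      if p.t > default_spec.t_cyl + 0.8 * default_spec.t_cap}
        assert any(a in tip_chains or b in tip_chains for a, b, *_ in report)


class TestModelMass:
    def test_published_consistency(self, full_shell):
        # 12.2 MDa / 1730 monomers back-computes the per-monomer mass
        per_monomer = 12.2e6 / 1730
        assert builder.model_mass(full_shell, per_monomer) == pytest.approx(1.22e7)

    def test_single_monomer(self, toy_template):
        model = builder.ShellModel(
            placements=[builder.Placement(t=0.0, rotation=np.eye(3),
                                          translation=np.zeros(3))],
            template=toy_template)
        assert builder.model_mass(model) == pytest.approx(toy_template.mass)

    def test_half_vs_full_factor_two(self, half_shell, full_shell):
        assert builder.model_mass(full_shell) == pytest.approx(
            2 * builder.model_mass(half_shell))


class TestWriteStructure:
    def test_segment_as_pdb(self, toy_template, tmp_path):
        model = builder.helical_expand(toy_template, 0.525, -3.874, 15)
        path = tmp_path / "segment.pdb"
        builder.write_structure(model, path)
        loaded = read_structure_file(path)
        assert loaded.array_length() == 15 * toy_template.n_atoms
        assert sorted(set(loaded.chain_id)) == list("ABCDEFGHIJKLMNO")

    def test_full_model_cif_round_trip(self, toy_template, tmp_path):
        spec = geometry.VesicleSpec(spacing=200.0)
        model = builder.duplicate_d1(
            builder.build_half_shell(toy_template, spec))
        path = tmp_path / "vesicle.cif"
        builder.write_structure(model, path)
        loaded = read_structure_file(path)
        assert loaded.array_length() == model.n_monomers * toy_template.n_atoms
        np.testing.assert_allclose(np.asarray(loaded.coord),
                                   model.all_coords(), atol=2e-3)

    def test_oversized_pdb_rejected(self, full_shell, tmp_path):
        with pytest.raises(ValueError, match="PDB|chain"):
            builder.write_structure(full_shell, tmp_path / "vesicle.pdb")

    def test_empty_model_rejected(self, toy_template, tmp_path):
        model = builder.ShellModel(placements=[], template=toy_template)
        with pytest.raises(ValueError):
            builder.write_structure(model, tmp_path / "empty.cif")
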