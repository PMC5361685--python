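import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dnaenm.helix import (
    HelicalParameterSet,
    PlacementConfig,
    build_basic_structure,
    default_helical_parameters,
    export_structure,
    load_helical_parameters,
)
from dnaenm.sequence import DnaSequence

FULL_TABLE = """step twist roll tilt shift slide rise
AA 35.1 0.7 -1.4 -0.03 -0.08 3.27
AC 31.5 0.7 -0.1 0.13 -0.58 3.36
AG 31.9 4.5 -1.7 0.09 -0.25 3.34
AT 29.3 1.1 0.0 0.00 -0.59 3.31
CA 34.5 4.7 0.5 0.09 0.53 3.33
CC 33.7 3.6 -0.1 0.05 -0.22 3.42
CG 36.1 5.4 0.0 0.00 0.41 3.39
GA 36.9 1.9 -1.5 -0.28 0.09 3.37
GC 40.0 0.3 0.0 0.00 -0.38 3.40
TA 37.8 3.3 0.0 0.00 0.05 3.42
"""


class TestLoadParameters:
    def test_ten_unique_steps_complete_to_sixteen(self):
        ps = load_helical_parameters(FULL_TABLE)
        assert len(ps.steps) == 16

    def test_complementary_sign_convention(self):
        ps = load_helical_parameters(FULL_TABLE)
        aa, tt = ps.step("AA"), ps.step("TT")
        assert tt["twist"] == aa["twist"]
        assert tt["roll"] == aa["roll"]
        assert tt["rise"] == aa["rise"]
        assert tt["slide"] == aa["slide"]
        assert tt["tilt"] == -aa["tilt"]
        assert tt["shift"] == -aa["shift"]

    def test_complement_roundtrip_rebuild(self):
        """Auto-filled steps reproduce the original under double complementation."""
        ps = load_helical_parameters(FULL_TABLE)
        from dnaenm.helix import _complement_params, _revcomp_step

        for name, rec in ps.steps.items():
            back = _complement_params(ps.steps[_revcomp_step(name)])
            for f, v in rec.items():
                assert back[f] == pytest.approx(v, abs=1e-12)

    def test_uniform_ideal_table(self):
        ps = HelicalParameterSet.ideal_b(36.0, 3.4)
        assert len(ps.steps) == 16
        assert all(p["twist"] == 36.0 and p["rise"] == 3.4 for p in ps.steps.values())

    def test_non_numeric_field_reports_line(self):
        bad = FULL_TABLE.replace("35.1", "abc")
        with pytest.raises(ValueError, match="line 2"):
            load_helical_parameters(bad)

    def test_missing_step_named(self):
        # drop AA (and thereby TT) from the table
        lines = [l for l in FULL_TABLE.splitlines() if not l.startswith("AA")]
        with pytest.raises(ValueError, match="AA"):
            load_helical_parameters("\n".join(lines))

    def test_inconsistent_complement_pair_rejected(self):
        bad = FULL_TABLE + "TT 35.1 0.7 -1.4 -0.03 -0.08 3.27\n"  # tilt not negated
        with pytest.raises(ValueError, match="sign convention"):
            load_helical_parameters(bad)

    def test_packaged_default_loads(self):
        ps = default_helical_parameters()
        assert len(ps.steps) == 16
        assert ps.step("GC")["twist"] == pytest.approx(40.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_tables_complete_consistently(self, seed):
        """Any 10-unique-step table completes to a valid 16-step set."""
        rng = np.random.default_rng(seed)
        lines = ["step twist roll tilt shift slide rise"]
        for step in ("AA", "AC", "AG", "AT", "CA", "CC", "CG", "GA", "GC", "TA"):
            tw, ro, ti = rng.uniform(20, 45), rng.uniform(-8, 8), rng.uniform(-3, 3)
            sh, sl, ri = rng.uniform(-0.5, 0.5), rng.uniform(-1, 1), rng.uniform(3, 3.6)
            if step in ("AT", "CG", "GC", "TA"):  # self-complementary steps
                ti = sh = 0.0
            lines.append(f"{step} {tw:.3f} {ro:.3f} {ti:.3f} {sh:.3f} {sl:.3f} {ri:.3f}")
        ps = load_helical_parameters("\n".join(lines))
        assert len(ps.steps) == 16  # validation in the constructor passed


class TestBuildStructure:
    def test_pure_twist_rise_helix(self):
        """Uniform 36 deg / 3.4 A: colinear origins, 10-step periodicity."""
        s = build_basic_structure(DnaSequence("A" * 11), HelicalParameterSet.ideal_b())
        spacing = np.linalg.norm(np.diff(s.origins, axis=0), axis=1)
        np.testing.assert_allclose(spacing, 3.4, atol=1e-12)
        # all origins on the z axis
        np.testing.assert_allclose(s.origins[:, :2], 0.0, atol=1e-12)
        # 10 x 36 deg = full turn
        np.testing.assert_allclose(s.frames[10], s.frames[0], atol=1e-6)

    def test_ideal_pitch_and_end_to_end(self):
        """Pitch = 360/twist steps and end-to-end = (N-1)*rise, exactly."""
        twist, rise, n = 30.0, 3.2, 25
        s = build_basic_structure(
            DnaSequence("G" * n), HelicalParameterSet.ideal_b(twist, rise)
        )
        assert 360.0 / twist == pytest.approx(12.0)
        np.testing.assert_allclose(s.frames[12], s.frames[0], atol=1e-9)
        assert np.linalg.norm(s.origins[-1] - s.origins[0]) == pytest.approx(
            (n - 1) * rise, abs=1e-9
        )

    def test_too_short_and_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_basic_structure(DnaSequence("A"))
        with pytest.raises(ValueError, match="resolve"):
            build_basic_structure(DnaSequence("ACNGT"))

    def test_intra_pair_distance_invariant(self, crystal_structure_30bp):
        d = np.linalg.norm(
            crystal_structure_30bp.coords_w - crystal_structure_30bp.coords_c, axis=1
        )
        np.testing.assert_allclose(d, PlacementConfig().pair_distance, atol=1e-9)

    def test_frames_orthonormal(self, crystal_structure_30bp):
        f = crystal_structure_30bp.frames
        eye = np.einsum("nij,nkj->nik", f, f)
        np.testing.assert_allclose(eye, np.broadcast_to(np.eye(3), eye.shape), atol=1e-9)
        assert np.all(np.linalg.det(f) > 0.99)

    def test_deterministic(self):
        seq = DnaSequence("ACGTACGTAACC")
        a = build_basic_structure(seq)
        b = build_basic_structure(seq)
        assert np.array_equal(a.coords_w, b.coords_w)
        assert np.array_equal(a.coords_c, b.coords_c)

    def test_independent_frame_composition_oracle(self, rng):
        """Coordinates match a direct step-by-step rotation-matrix product."""
        from dnaenm.sequence import random_sequence

        seq = random_sequence(40, rng)
        ps = default_helical_parameters()
        s = build_basic_structure(seq, ps)

        def rotz(a):
            c, si = math.cos(a), math.sin(a)
            return np.array([[c, -si, 0], [si, c, 0], [0, 0, 1]])

        def roty(a):
            c, si = math.cos(a), math.sin(a)
            return np.array([[c, 0, si], [0, 1, 0], [-si, 0, c]])

        frame = np.eye(3)
        origin = np.zeros(3)
        for i in range(len(seq) - 1):
            p = ps.step(seq.bases[i : i + 2])
            om = math.radians(p["twist"])
            gamma = math.hypot(math.radians(p["roll"]), math.radians(p["tilt"]))
            phi = math.atan2(math.radians(p["tilt"]), math.radians(p["roll"]))
            mid = frame @ rotz(om / 2 - phi) @ roty(gamma / 2) @ rotz(phi)
            origin = origin + mid @ [p["shift"], p["slide"], p["rise"]]
            frame = frame @ rotz(om / 2 - phi) @ roty(gamma) @ rotz(om / 2 + phi)
            np.testing.assert_allclose(s.origins[i + 1], origin, atol=1e-9)
            np.testing.assert_allclose(s.frames[i + 1], frame, atol=1e-9)

    def test_atom_radius_in_bdna_range(self, crystal_structure_30bp):
        """Pseudo-atoms stay within a B-DNA-like distance of the local axis."""
        s = crystal_structure_30bp
        r = np.linalg.norm(s.coords_w - s.origins, axis=1)
        assert np.all((r > 4.0) & (r < 9.0))

    def test_rigid_body_invariance(self):
        """Prepending a rotation+translation to the first frame moves all atoms rigidly."""
        seq = DnaSequence("ACGTTACGGA")
        base = build_basic_structure(seq)
        rot = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        shift = np.array([5.0, -2.0, 11.0])
        moved = build_basic_structure(seq, initial_frame=rot, initial_origin=shift)
        for arr_base, arr_moved in (
            (base.coords_w, moved.coords_w),
            (base.coords_c, moved.coords_c),
            (base.origins, moved.origins),
        ):
            np.testing.assert_allclose(arr_moved, arr_base @ rot.T + shift, atol=1e-9)

    def test_reverse_complement_superimposable(self, rng):
        """Rebuilding the reverse complement gives the same double helix."""
        from dnaenm.sequence import random_sequence

        seq = random_sequence(25, rng)
        a = build_basic_structure(seq)
        b = build_basic_structure(seq.reverse_complement())
        # pair i of the reverse complement is pair L-1-i with strands swapped
        x = np.concatenate([a.coords_w, a.coords_c])
        y = np.concatenate([b.coords_c[::-1], b.coords_w[::-1]])
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rot, rssd = Rotation.align_vectors(xc, yc)
        rmsd = np.sqrt(np.mean(np.sum((rot.apply(yc) - xc) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_nonzero_intra_pair_parameters_change_atoms_not_frames(self):
        ps = default_helical_parameters()
        intra = {b: dict(buckle=0.0, propeller=-12.0, opening=0.0,
                         shear=0.0, stretch=0.0, stagger=0.1) for b in "ACGT"}
        ps2 = HelicalParameterSet(ps.steps, intra)
        seq = DnaSequence("ACGTAC")
        flat = build_basic_structure(seq, ps)
        prop = build_basic_structure(seq, ps2)
        np.testing.assert_allclose(flat.frames, prop.frames, atol=1e-12)
        assert np.abs(flat.coords_w - prop.coords_w).max() > 0.05


class TestExport:
    def test_pdb_record_counts_and_roundtrip(self, tmp_path):
        s = build_basic_structure(DnaSequence("ACG"))
        path = tmp_path / "s.pdb"
        export_structure(s, path)
        lines = path.read_text().splitlines()
        atoms = [l for l in lines if l.startswith("ATOM")]
        assert len(atoms) == 6
        assert {l[21] for l in atoms} == {"A", "B"}
        xyz = np.array([[float(l[30:38]), float(l[38:46]), float(l[46:54])] for l in atoms])
        ref = np.vstack([s.coords_w, s.coords_c])
        np.testing.assert_allclose(xyz, ref, atol=1.5e-3)  # format precision

    def test_empty_structure_rejected(self, tmp_path):
        import dataclasses

        s = build_basic_structure(DnaSequence("ACG"))
        empty = dataclasses.replace(
            s, sequence="", coords_w=s.coords_w[:0], coords_c=s.coords_c[:0]
        )
        target = tmp_path / "none.pdb"
        with pytest.raises(ValueError):
            export_structure(empty, target)
        assert not target.exists()
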