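import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confsel.structure import (
    AtomRecord,
    HelixSegment,
    Structure,
    backbone_rmsd,
    fit_helix_axis,
    interhelical_angle,
    pairwise_rmsd_matrix,
    perpendicular_axes,
    read_pdb,
    rotate_segment,
    rotation_matrix,
    superpose,
    write_pdb,
)
from confsel.synthetic import build_ideal_helix


def make_helix(n=10, chain="A"):
    return build_ideal_helix("A" * n, chain_id=chain)


class TestAtomRecord:
    def test_rejects_nonfinite_position(self):
        with pytest.raises(ValueError, match="non-finite"):
            AtomRecord(1, "A", 1, "ALA", "CA", np.array([0.0, np.nan, 0.0]))

    def test_duplicate_key_rejected(self):
        rec = AtomRecord(1, "A", 1, "ALA", "CA", np.zeros(3))
        with pytest.raises(ValueError, match="duplicate"):
            Structure([rec, rec])


class TestPdbIO:
    def test_multimodel_roundtrip(self, tmp_path):
        h = make_helix()
        recs = []
        for m in (1, 2):
            for r in h.atom_records():
                recs.append(AtomRecord(m, r.chain_id, r.residue_number, r.residue_name, r.atom_name, r.position + (m - 1)))
        s = Structure(recs)
        path = tmp_path / "two.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert back.models == [1, 2]
        back.validate()
        assert np.abs(back.xyz - s.xyz).max() < 1e-3  # PDB has 3 decimals

    def test_single_model_no_model_card(self, tmp_path):
        h = make_helix(6)
        path = tmp_path / "one.pdb"
        write_pdb(h, path)
        text = path.read_text()
        assert "MODEL" not in text
        back = read_pdb(path)
        assert back.models == [1]

    def test_model_selection(self, tmp_path):
        h = make_helix()
        recs = [r for r in h.atom_records()]
        recs += [AtomRecord(2, r.chain_id, r.residue_number, r.residue_name, r.atom_name, r.position) for r in h.atom_records()]
        path = tmp_path / "m.pdb"
        write_pdb(Structure(recs), path)
        assert read_pdb(path, model_selection="first").models == [1]
        assert read_pdb(path, model_selection=2).models == [1]  # renumbered on extract
        with pytest.raises(ValueError):
            read_pdb(path, model_selection=9)

    def test_unparsable_line_reports_error(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  CA  ALA A   1      xxx.000   0.000   0.000  1.00  0.00           C\nEND\n")
        with pytest.raises(ValueError, match="format error"):
            read_pdb(path)

    def test_hetatm_excluded(self, tmp_path):
        h = make_helix(5)
        path = tmp_path / "het.pdb"
        write_pdb(h, path)
        lines = path.read_text().splitlines()
        lines.insert(-1, "HETATM  999  O   HOH A 900      10.000  10.000  10.000  1.00  0.00           O")
        path.write_text("\n".join(lines) + "\n")
        back = read_pdb(path)
        assert all(r[1] != "HOH" for r in back.residues())


class TestHelixAxis:
    def test_axis_along_construction_direction(self):
        # 19 CA atoms = 18 intervals = 5 full turns: the end-to-end CA chord
        # coincides with the true helix axis
        h = make_helix(19)
        seg = fit_helix_axis(h, 1, "A", 1, 19)
        ca = h.coords(model=1, atom_names=["CA"])
        direction = ca[-1] - ca[0]
        direction /= np.linalg.norm(direction)
        ang = np.degrees(np.arccos(np.clip(seg.axis @ direction, -1, 1)))
        assert ang < 2.0

    def test_rotation_equivariance_translation_invariance(self):
        h = make_helix(8)
        R = rotation_matrix(np.array([1.0, 2.0, -0.5]), 63.0)
        shift = np.array([5.0, -3.0, 11.0])
        moved = h.with_coords(h.xyz @ R.T + shift)
        a0 = fit_helix_axis(h, 1, "A", 1, 8).axis
        a1 = fit_helix_axis(moved, 1, "A", 1, 8).axis
        assert np.allclose(a1, R @ a0, atol=1e-9)

    def test_missing_ca_listed(self):
        h = make_helix(6)
        recs = [r for r in h.atom_records() if not (r.residue_number == 3 and r.atom_name == "CA")]
        s = Structure(recs)
        with pytest.raises(ValueError, match=r"\[3\]"):
            fit_helix_axis(s, 1, "A", 1, 6)

    def test_too_short(self):
        h = make_helix(6)
        with pytest.raises(ValueError, match=">= 4"):
            fit_helix_axis(h, 1, "A", 1, 3)


class TestInterhelicalAngle:
    def seg(self, axis):
        axis = np.asarray(axis, float)
        return HelixSegment("A", 1, 5, axis / np.linalg.norm(axis), np.zeros(3))

    def test_parallel_zero(self):
        assert interhelical_angle(self.seg([0, 0, 1]), self.seg([0, 0, 1])) == pytest.approx(0.0)

    def test_antiparallel_180(self):
        assert interhelical_angle(self.seg([0, 0, 1]), self.seg([0, 0, -1])) == pytest.approx(180.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=3), rng.normal(size=3)
        s1, s2 = self.seg(a), self.seg(b)
        t12 = interhelical_angle(s1, s2)
        assert t12 == pytest.approx(interhelical_angle(s2, s1))
        assert 0.0 <= t12 <= 180.0


class TestRotateSegment:
    @pytest.fixture()
    def segs(self, bound_peptide):
        h1 = fit_helix_axis(bound_peptide, 1, "B", 786, 790)
        h2 = fit_helix_axis(bound_peptide, 1, "B", 799, 808)
        return h1, h2

    def test_zero_angle_identity(self, bound_peptide, segs):
        h1, h2 = segs
        out = rotate_segment(bound_peptide, h1, h2, 0.0, 1)
        assert np.abs(out.xyz - bound_peptide.xyz).max() < 1e-12

    @pytest.mark.parametrize("axis_index", [1, 2, 3, 4])
    def test_rigidity(self, bound_peptide, segs, axis_index):
        h1, h2 = segs
        out = rotate_segment(bound_peptide, h1, h2, 77.0, axis_index)
        sel = dict(chain="B", residues=range(786, 791))
        a = bound_peptide.coords(**sel)
        b = out.coords(**sel)
        da = np.linalg.norm(a[:, None] - a[None], axis=-1)
        db = np.linalg.norm(b[:, None] - b[None], axis=-1)
        assert np.abs(da - db).max() < 1e-6

    def test_inverse(self, bound_peptide, segs):
        h1, h2 = segs
        out = rotate_segment(rotate_segment(bound_peptide, h1, h2, 30.0, 2), h1, h2, -30.0, 2)
        assert np.abs(out.xyz - bound_peptide.xyz).max() < 1e-9

    def test_perpendicular_axis_changes_theta_by_rotation(self, bound_peptide, segs):
        # axis 3 is perpendicular to both helices: theta shifts by exactly 30 deg
        h1, h2 = segs
        theta0 = interhelical_angle(h1, h2)
        out = rotate_segment(bound_peptide, h1, h2, 30.0, 3)
        theta = interhelical_angle(fit_helix_axis(out, 1, "B", 786, 790), h2)
        assert abs(abs(theta - theta0) - 30.0) < 1.0

    @pytest.mark.parametrize("axis_index", [1, 2, 3, 4])
    def test_all_axes_perturb_theta(self, bound_peptide, segs, axis_index):
        h1, h2 = segs
        theta0 = interhelical_angle(h1, h2)
        out = rotate_segment(bound_peptide, h1, h2, 30.0, axis_index)
        theta = interhelical_angle(fit_helix_axis(out, 1, "B", 786, 790), h2)
        assert 0.0 < abs(theta - theta0) <= 31.0

    def test_axes_are_perpendicular_and_distinct(self, segs):
        h1, h2 = segs
        axes = perpendicular_axes(h2.axis, 4, anchor=h1.axis)
        assert np.abs(axes @ h2.axis).max() < 1e-9
        for i in range(4):
            for j in range(i + 1, 4):
                assert abs(abs(axes[i] @ axes[j]) - 1.0) > 1e-6

    def test_nonfinite_angle_rejected(self, bound_peptide, segs):
        h1, h2 = segs
        with pytest.raises(ValueError):
            rotate_segment(bound_peptide, h1, h2, float("nan"), 1)


class TestRmsd:
    def _ensemble(self, n_models, perturb=0.0, rigid=False, seed=0):
        rng = np.random.default_rng(seed)
        h = make_helix(10)
        recs = []
        for m in range(1, n_models + 1):
            xyz = h.xyz
            if rigid and m > 1:
                R = rotation_matrix(rng.normal(size=3), rng.uniform(10, 120))
                xyz = xyz @ R.T + rng.normal(size=3) * 10
            if perturb and m > 1:
                xyz = xyz + rng.normal(0, perturb, xyz.shape)
            for r, p in zip(h.atom_records(), xyz):
                recs.append(AtomRecord(m, r.chain_id, r.residue_number, r.residue_name, r.atom_name, p))
        return Structure(recs)

    def test_identical_copies_zero(self):
        s = self._ensemble(4)
        assert backbone_rmsd(s, (1, 10), "A") == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_zero(self):
        s = self._ensemble(3, rigid=True)
        assert backbone_rmsd(s, (1, 10), "A") == pytest.approx(0.0, abs=1e-6)

    def test_superposed_not_larger_than_raw(self):
        s = self._ensemble(5, perturb=0.5, rigid=True, seed=3)
        from confsel.structure import model_coords

        coords = model_coords(s, chain="A", residues=range(1, 11))
        raw = np.mean(
            [np.sqrt(np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1))) for i in range(5) for j in range(i + 1, 5)]
        )
        assert backbone_rmsd(s, (1, 10), "A") <= raw + 1e-12

    def test_modes_similar_scale(self):
        s = self._ensemble(6, perturb=0.4, seed=1)
        pw = backbone_rmsd(s, (1, 10), "A", mode="pairwise_mean")
        tm = backbone_rmsd(s, (1, 10), "A", mode="to_mean")
        assert 0 < tm < pw < 2 * tm + 1e-9  # pairwise mean exceeds spread about the mean

    def test_single_model_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            backbone_rmsd(make_helix(5), (1, 5), "A")

    def test_pairwise_matrix_matches_superpose(self):
        s = self._ensemble(4, perturb=0.7, seed=5)
        from confsel.structure import model_coords

        coords = model_coords(s, chain="A", residues=range(1, 11))
        D = pairwise_rmsd_matrix(coords)
        for i in range(4):
            for j in range(4):
                _, ref = superpose(coords[i], coords[j])
                assert D[i, j] == pytest.approx(ref, abs=1e-9)
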