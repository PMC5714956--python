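import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confsel.shifts import (
    AA3,
    JCoupling,
    ShiftRecord,
    ShiftTable,
    csi,
    csp,
    helix_population_from_J,
    karplus_3J,
    load_random_coil_j,
    load_random_coil_table,
    noe_ratio_classify,
    read_nmrstar_shifts,
    read_shift_tsv,
    secondary_shifts,
    ssp,
    write_shift_tsv,
)
from confsel.rdc import SaupeTensor
from confsel.synthetic import PeptideSpec, SimulationConfig, simulate_shifts


def coil_table(sequence3, rc, start=1):
    recs = []
    for i, rt in enumerate(sequence3):
        for atom in ("CA", "CB", "HA"):
            v = rc.rc(rt, atom)
            if v is not None:
                recs.append(ShiftRecord(start + i, rt, atom, v))
    return ShiftTable(recs)


def helix_fraction_table(sequence3, rc, p, start=1):
    recs = []
    for i, rt in enumerate(sequence3):
        for atom in ("CA", "CB", "HA"):
            v = rc.rc(rt, atom)
            if v is None:
                continue
            recs.append(ShiftRecord(start + i, rt, atom, v + p * rc.helix_full(rt, atom)))
    return ShiftTable(recs)


SEQ = [AA3[i % 17] for i in range(15)]  # mixed residue types, no edge cases


class TestRandomCoilTable:
    def test_complete_for_standard_residues(self, rc_table):
        for res in AA3:
            assert rc_table.rc(res, "CA") is not None
            assert rc_table.rc(res, "HA") is not None
            if res != "GLY":
                assert rc_table.rc(res, "CB") is not None

    def test_gly_has_no_cb(self, rc_table):
        assert rc_table.rc("GLY", "CB") is None


class TestSecondaryShifts:
    def test_coil_input_all_zero(self, rc_table):
        table = coil_table(SEQ, rc_table)
        sec = secondary_shifts(table, rc_table)
        assert np.nanmax(np.abs(sec[["dd_CA", "dd_CB", "dd_HA"]].to_numpy(float))) == pytest.approx(0.0)

    def test_fractional_helix_construction(self, rc_table):
        table = helix_fraction_table(SEQ, rc_table, 0.3)
        sec = secondary_shifts(table, rc_table)
        for _, row in sec.iterrows():
            for atom in ("CA", "CB", "HA"):
                full = rc_table.helix_full(row.residue_name, atom)
                if full is None:
                    continue
                assert row[f"dd_{atom}"] / full == pytest.approx(0.3)

    def test_unknown_residue_type(self, rc_table):
        table = ShiftTable([ShiftRecord(1, "XXX", "CA", 55.0)])
        with pytest.raises(ValueError, match="unknown residue type"):
            secondary_shifts(table, rc_table)

    def test_missing_values_reported(self, rc_table):
        table = ShiftTable([ShiftRecord(1, "ALA", "CA", 52.5), ShiftRecord(2, "GLY", "CA", 45.1)])
        sec = secondary_shifts(table, rc_table)
        assert (2, "CB") in sec.attrs["skipped"]


class TestSSP:
    def test_coil_near_zero(self, rc_table):
        prof = ssp(coil_table(SEQ, rc_table), rc_table)
        assert np.nanmax(np.abs(prof.scores.to_numpy())) < 0.05

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 1.0])
    def test_population_recovery_interior(self, rc_table, p):
        # interior residues (full window inside the segment) recover p exactly;
        # edge residues are diluted by coil neighbours
        table = helix_fraction_table(SEQ, rc_table, p)
        prof = ssp(table, rc_table, window=5)
        interior = prof.scores.iloc[2:-2]
        assert np.allclose(interior, p, atol=0.05)

    def test_strand_scores_negative(self, rc_table):
        recs = []
        for i, rt in enumerate(SEQ):
            for atom in ("CA", "CB", "HA"):
                v = rc_table.rc(rt, atom)
                if v is None:
                    continue
                recs.append(ShiftRecord(1 + i, rt, atom, v + 0.5 * rc_table.strand_full(rt, atom)))
        prof = ssp(ShiftTable(recs), rc_table)
        assert np.allclose(prof.scores.iloc[2:-2], -0.5, atol=0.05)

    def test_window_validation(self, rc_table):
        table = coil_table(SEQ, rc_table)
        with pytest.raises(ValueError):
            ssp(table, rc_table, window=4)

    def test_insufficient_data(self, rc_table):
        table = ShiftTable([ShiftRecord(1, "ALA", "CA", 52.5)])
        with pytest.raises(ValueError, match="not enough"):
            ssp(table, rc_table)

    def test_agrees_with_j_populations(self, rc_table, generator_tensor):
        # same planted populations -> SSP and J-based estimates agree within 0.1
        spec = PeptideSpec(p1=0.2, p2=0.6)
        cfg = SimulationConfig(tensor=generator_tensor, noise_shift_h=0.0, noise_shift_heavy=0.0, noise_j=0.0, rng_seed=0)
        table, couplings = simulate_shifts(spec, rc_table, cfg)
        prof = ssp(table, rc_table)
        restypes = {r: table.residue_name(r) for r in table.residues}
        pops = helix_population_from_J(couplings, restypes).set_index("residue_number")
        for lo, hi, p in [(spec.helix1[0], spec.helix1[1], 0.2), (spec.helix2[0], spec.helix2[1], 0.6)]:
            for r in range(lo + 2, hi - 1):
                assert abs(prof.scores[r] - pops.at[r, "population"]) < 0.1


class TestCSI:
    def test_full_helix_consensus(self, rc_table):
        table = helix_fraction_table(SEQ, rc_table, 1.0)
        out = csi(table, rc_table)
        assert set(out.consensus.iloc[1:-1]) == {"H"}

    def test_coil_consensus(self, rc_table):
        out = csi(coil_table(SEQ, rc_table), rc_table)
        assert set(out.consensus) == {"C"}

    def test_short_runs_suppressed(self, rc_table):
        # 3 helix-like residues in a coil background: below the 4-run rule
        recs = []
        for i, rt in enumerate(SEQ):
            p = 1.0 if i in (5, 6, 7) else 0.0
            for atom in ("CA", "CB", "HA"):
                v = rc_table.rc(rt, atom)
                if v is None:
                    continue
                recs.append(ShiftRecord(1 + i, rt, atom, v + p * rc_table.helix_full(rt, atom)))
        out = csi(ShiftTable(recs), rc_table)
        assert "H" not in set(out.consensus)


class TestJCouplings:
    def test_karplus_values(self):
        assert karplus_3J(-57.0) == pytest.approx(3.74, abs=0.01)
        assert karplus_3J(-120.0) == pytest.approx(9.87, abs=1e-9)

    @given(st.floats(-180, 180))
    @settings(max_examples=100, deadline=None)
    def test_karplus_cosine_symmetry(self, phi):
        # J(phi) == J(phi') whenever cos(phi-60) matches: reflect about 60 deg
        mirrored = 120.0 - phi
        assert karplus_3J(phi) == pytest.approx(karplus_3J(mirrored), abs=1e-9)

    def test_population_endpoints(self):
        restypes = {1: "ALA", 2: "ALA"}
        j_coil = load_random_coil_j()
        out = helix_population_from_J(
            [JCoupling(1, j_coil["ALA"]), JCoupling(2, 4.0)], restypes, j_helix=4.0
        ).set_index("residue_number")
        assert out.at[1, "population"] == pytest.approx(0.0)
        assert out.at[2, "population"] == pytest.approx(1.0)

    def test_population_mixture(self):
        j_coil = {"ALA": 7.0}
        j_obs = 0.7 * 7.0 + 0.3 * 4.0
        out = helix_population_from_J([JCoupling(1, j_obs)], {1: "ALA"}, j_helix=4.0, j_coil=j_coil)
        assert out.population.iloc[0] == pytest.approx(0.3)

    def test_degenerate_references_rejected(self):
        with pytest.raises(ValueError):
            helix_population_from_J([JCoupling(1, 5.0)], {1: "ALA"}, j_helix=7.0, j_coil={"ALA": 7.0})

    def test_clipping_flagged(self):
        out = helix_population_from_J([JCoupling(1, 2.0)], {1: "ALA"}, j_helix=4.0, j_coil={"ALA": 7.0})
        assert bool(out.clipped.iloc[0]) and out.population.iloc[0] == 1.0


class TestNoeRatios:
    def test_reference_values(self):
        out = noe_ratio_classify({1: 0.25, 2: 1.4, 3: 55.0}).set_index("residue_number")
        assert out.at[1, "class"] == "helix" and out.at[1, "helix_fraction"] == pytest.approx(1.0)
        assert out.at[2, "class"] == "coil" and out.at[2, "helix_fraction"] == pytest.approx(0.0)
        assert out.at[3, "class"] == "strand"

    def test_log_interpolation(self):
        mid = math.exp(0.5 * (math.log(0.25) + math.log(1.4)))
        out = noe_ratio_classify({1: mid})
        assert out.helix_fraction.iloc[0] == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            noe_ratio_classify({1: 0.0})


class TestCSP:
    def amide_table(self, shifts):
        recs = []
        for res, (hn, n) in shifts.items():
            recs.append(ShiftRecord(res, "ALA", "HN", hn))
            recs.append(ShiftRecord(res, "ALA", "N", n))
        return ShiftTable(recs)

    def test_identical_tables_zero(self):
        t = self.amide_table({1: (8.1, 119.0), 2: (8.3, 121.0)})
        table, mean = csp(t, t)
        assert table.delta_obs.max() == 0.0 and mean == 0.0

    def test_hand_value_eq1(self):
        free = self.amide_table({1: (8.0, 119.0)})
        bound = self.amide_table({1: (8.1, 119.5)})
        table, _ = csp(free, bound)
        assert table.delta_obs.iloc[0] == pytest.approx(0.1)

    def test_hand_value_nitrogen_only(self):
        free = self.amide_table({1: (8.0, 119.0)})
        bound = self.amide_table({1: (8.0, 120.0)})
        table, _ = csp(free, bound)
        assert table.delta_obs.iloc[0] == pytest.approx(math.sqrt(0.04 / 2.0))

    def test_swap_invariant(self):
        free = self.amide_table({1: (8.0, 119.0), 2: (8.4, 122.0)})
        bound = self.amide_table({1: (8.2, 118.0), 2: (8.1, 125.0)})
        t1, m1 = csp(free, bound)
        t2, m2 = csp(bound, free)
        pd.testing.assert_frame_equal(t1, t2)
        assert m1 == m2

    def test_unmatched_residue_excluded(self):
        free = self.amide_table({1: (8.0, 119.0), 2: (8.4, 122.0)})
        bound = self.amide_table({1: (8.2, 118.0)})
        table, _ = csp(free, bound)
        assert table.attrs["excluded"] == [2]
        assert table.residue_number.tolist() == [1]


class TestIO:
    def test_tsv_roundtrip(self, tmp_path, rc_table):
        table = coil_table(SEQ, rc_table)
        path = tmp_path / "shifts.tsv"
        write_shift_tsv(table, path)
        back = read_shift_tsv(path)
        assert len(back) == len(table)
        assert back.get(1, "CA") == table.get(1, "CA")

    def test_nmrstar_reader(self, tmp_path):
        star = """\
data_test
save_assigned_chemical_shifts
   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Entity_ID
      _Atom_chem_shift.Seq_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Atom_type
      _Atom_chem_shift.Val
      _Atom_chem_shift.Val_err

     1 1 257 GLY CA C 45.2 0.1
     2 1 258 ALA CA C 52.9 0.1
     3 1 258 ALA H  H  8.25 0.02
     4 1 258 ALA N  N 120.4 0.1
     5 1 258 ALA HB H  1.35 0.02
   stop_
save_
"""
        path = tmp_path / "entry.str"
        path.write_text(star)
        table = read_nmrstar_shifts(path)
        assert table.get(257, "CA") == 45.2
        assert table.get(258, "HN") == 8.25
        assert table.get(258, "N") == 120.4
        # side-chain protons are not retained
        assert len(table) == 4


class TestShiftRecordValidation:
    def test_window_enforced(self):
        with pytest.raises(ValueError, match="plausible window"):
            ShiftRecord(1, "ALA", "CA", 120.0)
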