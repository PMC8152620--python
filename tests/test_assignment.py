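import itertools
import math

import numpy as np
import pytest

from autonmr.assignment import (
    AssignmentMatrix,
    CandidateShifts,
    assign_carbons,
    assign_hungarian,
    assign_protons,
    bias_reassign,
    boltzmann_average,
    build_matrix,
    multiple_assignment_penalty,
    read_shift_table,
    scale_external,
    scale_internal,
)
from autonmr.carbon import CarbonPeak
from autonmr.dp4 import ErrorModel, default_error_model
from autonmr.proton import Multiplet, PeakParams


def _mult(center, protons, height=100.0):
    return Multiplet([PeakParams(center, height, 1.2, 0.0)], 400.0, protons)


class TestBoltzmann:
    def test_single_conformer_unchanged(self):
        out = boltzmann_average([(0.0, {"C1": 10.0})])
        assert out == {"C1": 10.0}

    def test_equal_energies_mean(self):
        out = boltzmann_average([(0.0, {"C1": 10.0}), (0.0, {"C1": 20.0})])
        assert out["C1"] == pytest.approx(15.0)

    def test_rt_ln3_gives_three_to_one(self):
        rt = 8.31446261815324e-3 * 298.15
        de = rt * math.log(3.0)
        out = boltzmann_average([(0.0, {"C1": 1.0}), (de, {"C1": 2.0})])
        assert out["C1"] == pytest.approx(0.75 * 1.0 + 0.25 * 2.0)

    def test_nonfinite_energy_dropped(self):
        with pytest.warns(UserWarning):
            out = boltzmann_average(
                [(0.0, {"C1": 1.0}), (float("nan"), {"C1": 99.0})]
            )
        assert out["C1"] == pytest.approx(1.0)

    def test_shielding_reference_map(self):
        out = boltzmann_average(
            [(0.0, {"C1": 150.0})], shielding_reference=(180.0, 1.0)
        )
        assert out["C1"] == pytest.approx(30.0)


class TestScaling:
    def test_external_identity_and_linear(self):
        shifts = np.array([100.0])
        np.testing.assert_allclose(scale_external(shifts, (1.0, 0.0)), [100.0])
        assert scale_external(shifts, (1.05, 2.0))[0] == pytest.approx((100 - 2) / 1.05)

    def test_external_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            scale_external(np.array([1.0]), (0.0, 0.0))

    def test_internal_exact_regression(self):
        exp = np.linspace(10, 170, 12)
        pairs = [(1.05 * e + 2.0, e) for e in exp]
        slope, intercept = scale_internal(pairs)
        assert slope == pytest.approx(1.05, abs=1e-9)
        assert intercept == pytest.approx(2.0, abs=1e-6)

    def test_internal_outlier_downweighted(self):
        rng = np.random.default_rng(0)
        exp = np.linspace(10, 170, 15)
        pairs = [(1.05 * e + 2.0 + rng.normal(0, 0.05), e) for e in exp]
        pairs[4] = (pairs[4][0] + 30.0, pairs[4][1])  # gross outlier
        slope, _ = scale_internal(pairs)
        assert abs(slope - 1.05) < 0.05

    def test_internal_too_few_pairs_identity(self):
        with pytest.warns(UserWarning):
            assert scale_internal([(1.0, 1.0), (2.0, 2.0)]) == (1.0, 0.0)

    def test_internal_insane_slope_identity(self):
        pairs = [(3 * e, e) for e in (10.0, 50.0, 90.0, 130.0)]
        with pytest.warns(UserWarning):
            assert scale_internal(pairs) == (1.0, 0.0)


class TestMatrix:
    def test_gaussian_ratio(self):
        model = ErrorModel("C13", [(0.0, 2.5, 1.0)])
        m = build_matrix(
            np.array([50.0]), ["C1"], np.array([50.0, 55.0]), model, "C13"
        )
        ratio = m.entries[0, 0] / m.entries[0, 1]
        assert ratio == pytest.approx(math.exp(2.0), rel=1e-9)

    def test_diagonal_maximum_when_exact(self):
        model = default_error_model("C13")
        shifts = np.array([20.0, 80.0, 140.0])
        m = build_matrix(shifts, list("abc"), shifts, model, "C13")
        assert (np.argmax(m.entries, axis=1) == np.arange(3)).all()

    def test_penalty_monotone_in_t_and_k(self):
        assert multiple_assignment_penalty(0, 1) == 1.0
        for k in (1, 2, 3):
            vals = [multiple_assignment_penalty(t, k) for t in range(4)]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        assert multiple_assignment_penalty(1, 2) < multiple_assignment_penalty(1, 1)

    def test_proton_matrix_has_no_weights(self):
        model = default_error_model("H1")
        weights = np.array([0.01, 1.0])
        m_h = build_matrix(
            np.array([1.0]), ["H1a"], np.array([1.0, 2.0]), model, "H1",
            peak_weights=weights,
        )
        m_ref = build_matrix(
            np.array([1.0]), ["H1a"], np.array([1.0, 2.0]), model, "H1"
        )
        np.testing.assert_array_equal(m_h.entries, m_ref.entries)


class TestHungarian:
    def test_two_by_two_diagonal(self):
        m = AssignmentMatrix(
            np.array([[0.9, 0.1], [0.1, 0.9]]), ["a", "b"], [0, 1], [0, 0]
        )
        assert assign_hungarian(m) == [(0, 0), (1, 1)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.uniform(1e-3, 1.0, (6, 6))
        m = AssignmentMatrix(M, [f"s{i}" for i in range(6)], list(range(6)), [0] * 6)
        cost = sum(-math.log(M[i, j]) for i, j in assign_hungarian(m))
        best = min(
            sum(-math.log(M[i, p[i]]) for i in range(6))
            for p in itertools.permutations(range(6))
        )
        assert cost == pytest.approx(best, abs=1e-9)

    def test_more_shifts_than_peaks_with_replication(self):
        model = default_error_model("C13")
        peaks = np.array([30.0, 90.0, 150.0])
        shifts = np.array([29.0, 31.0, 89.0, 91.0, 149.0])
        m = build_matrix(
            shifts, [f"C{i}" for i in range(5)], peaks, model, "C13",
            peak_weights=np.ones(3), peak_groups=np.ones(3, int),
            replications=3,
        )
        match = assign_hungarian(m)
        assert len(match) == 5
        used = {}
        for row, col in match:
            used[m.column_peaks[col]] = used.get(m.column_peaks[col], 0) + 1
        assert max(used.values()) <= 3

    def test_too_few_columns_raises(self):
        m = AssignmentMatrix(np.ones((3, 2)), list("abc"), [0, 1], [0, 0])
        with pytest.raises(ValueError):
            assign_hungarian(m)


class TestCarbonStages:
    def test_linear_map_recovered(self):
        rng = np.random.default_rng(1)
        true = np.sort(rng.uniform(10, 180, 10))
        peaks = [CarbonPeak(float(p), 100.0) for p in true]
        calc = 1.05 * true + 2.0 + rng.normal(0, 0.3, 10)
        cs = CandidateShifts(
            "A", "C13", [(f"C{i:02d}", float(v)) for i, v in enumerate(calc)]
        )
        res = assign_carbons(cs, peaks, default_error_model("C13"))
        correct = sum(
            1 for i in range(10)
            if res.atoms[f"C{i:02d}"].peak_ppm == pytest.approx(true[i])
        )
        assert correct == 10
        stage, slope, intercept = res.scaling_stages[1]
        assert stage == "internal"
        assert slope == pytest.approx(1.05, abs=0.01)

    def test_degenerate_pair_assigned_twice(self):
        true = np.array([20.0, 50.0, 80.0, 110.0, 140.0, 140.0, 170.0, 30.0, 60.0])
        peak_pos = sorted(set(true))
        peaks = [CarbonPeak(float(p), 100.0) for p in peak_pos]
        cs = CandidateShifts(
            "A", "C13", [(f"C{i}", float(v) + 0.3) for i, v in enumerate(true)]
        )
        res = assign_carbons(cs, peaks, default_error_model("C13"))
        counts = res.assigned_counts(len(peaks))
        j140 = peak_pos.index(140.0)
        assert counts[j140] == 2
        assert all(c == 1 for i, c in enumerate(counts) if i != j140)

    def test_stage_idempotence_on_clean_data(self):
        true = np.linspace(20, 170, 8)
        peaks = [CarbonPeak(float(p), 100.0) for p in true]
        cs = CandidateShifts("A", "C13", [(f"C{i}", float(v)) for i, v in enumerate(true)])
        res = assign_carbons(cs, peaks, default_error_model("C13"))
        assignment = {l: a.peak_ppm for l, a in res.atoms.items()}
        res2 = assign_carbons(cs, peaks, default_error_model("C13"))
        assert assignment == {l: a.peak_ppm for l, a in res2.atoms.items()}
        assert res.reassignment_log == []

    def test_bias_rescues_missed_intense_peak(self):
        # shift sits on a weak noise-group peak while an intense peak 8 ppm
        # away is unassigned: bias > 1 must move it there
        peaks = [
            CarbonPeak(50.0, 10.0, amplitude_group=3, weight=0.05),
            CarbonPeak(58.0, 1000.0, amplitude_group=1, weight=1.0),
            CarbonPeak(120.0, 900.0, amplitude_group=1, weight=1.0),
        ]
        cs = CandidateShifts("A", "C13", [("C1", 50.1), ("C2", 120.0)])
        res = assign_carbons(cs, peaks, default_error_model("C13"))
        assert res.atoms["C1"].peak_ppm == pytest.approx(58.0)
        assert res.reassignment_log


class TestProtonAssignment:
    def test_methyl_trio_one_multiplet(self):
        mult = [_mult(1.0, 3), _mult(2.5, 2), _mult(4.0, 1)]
        atoms = [("H1", 0.95), ("H2", 0.98), ("H3", 1.02),
                 ("H4", 2.45), ("H5", 2.52), ("H6", 3.96)]
        cs = CandidateShifts("A", "H1", atoms, methyl_groups=[("H1", "H2", "H3")])
        res = assign_protons(cs, mult, default_error_model("H1"))
        assert {res.atoms[l].peak_ppm for l in ("H1", "H2", "H3")} == {1.0}
        assert res.atoms["H4"].peak_ppm == pytest.approx(2.5)
        assert res.atoms["H6"].peak_ppm == pytest.approx(4.0)

    def test_capacity_respected(self):
        mult = [_mult(1.0, 3), _mult(2.5, 2), _mult(4.0, 1)]
        atoms = [(f"H{i}", s) for i, s in enumerate(
            [0.9, 1.0, 1.1, 2.4, 2.5, 4.0]
        )]
        cs = CandidateShifts("A", "H1", atoms)
        res = assign_protons(cs, mult, default_error_model("H1"))
        counts = res.assigned_counts(3)
        assert counts[0] <= 3 and counts[1] <= 2 and counts[2] <= 1
        assert counts.sum() == 6

    def test_two_methyls_share_six_proton_singlet(self):
        mult = [_mult(1.1, 6), _mult(3.0, 1)]
        atoms = [(f"H{i}", 1.1 + 0.01 * i) for i in range(6)] + [("H9", 3.0)]
        cs = CandidateShifts(
            "A", "H1", atoms,
            methyl_groups=[("H0", "H1", "H2"), ("H3", "H4", "H5")],
        )
        res = assign_protons(cs, mult, default_error_model("H1"))
        for l in ("H0", "H1", "H2", "H3", "H4", "H5"):
            assert res.atoms[l].peak_ppm == pytest.approx(1.1)

    def test_labile_protons_excluded(self):
        mult = [_mult(1.0, 1), _mult(4.0, 1)]
        cs = CandidateShifts(
            "A", "H1", [("H1", 1.0), ("H2", 4.0), ("HO", 5.5)],
            labile_labels=frozenset({"HO"}),
        )
        res = assign_protons(cs, mult, default_error_model("H1"))
        assert "HO" not in res.atoms
        assert len(res.atoms) == 2

    def test_single_forced_match(self):
        res = assign_protons(
            CandidateShifts("A", "H1", [("H1", 2.0)]),
            [_mult(1.5, 1)],
            default_error_model("H1"),
        )
        assert res.atoms["H1"].peak_ppm == pytest.approx(1.5)

    def test_internal_scaling_fixed_point(self):
        # error-free linear data: a further pass changes nothing
        mult = [_mult(c, 1) for c in (1.0, 2.0, 4.0, 6.0, 8.5)]
        atoms = [(f"H{i}", 1.02 * c + 0.05) for i, c in enumerate((1.0, 2.0, 4.0, 6.0, 8.5))]
        cs = CandidateShifts("A", "H1", atoms)
        res = assign_protons(cs, mult, default_error_model("H1"))
        expected = dict(zip([f"H{i}" for i in range(5)], (1.0, 2.0, 4.0, 6.0, 8.5)))
        for l, a in res.atoms.items():
            assert a.peak_ppm == pytest.approx(expected[l])
        errs = np.abs(res.errors)
        assert errs.max() < 1e-6  # internal scaling removed the linear map


class TestShiftTable:
    def test_plain_table(self, tmp_path):
        p = tmp_path / "shifts.csv"
        p.write_text("atom_label,shift_ppm\nC1,12.3\nC2,77.1\n")
        cs = read_shift_table(p, nucleus="C13")
        assert cs.atoms == [("C1", 12.3), ("C2", 77.1)]

    def test_conformer_table_boltzmann(self, tmp_path):
        p = tmp_path / "conf.csv"
        p.write_text(
            "atom_label,shift_ppm,conformer_id,energy_kJmol\n"
            "C1,10.0,a,0.0\nC1,20.0,b,0.0\n"
        )
        cs = read_shift_table(p, nucleus="C13")
        assert dict(cs.atoms)["C1"] == pytest.approx(15.0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            CandidateShifts("A", "C13", [("C1", 1.0), ("C1", 2.0)])

    def test_overlapping_methyls_rejected(self):
        with pytest.raises(ValueError):
            CandidateShifts(
                "A", "H1", [("H1", 1.0), ("H2", 1.0), ("H3", 1.0), ("H4", 1.0)],
                methyl_groups=[("H1", "H2", "H3"), ("H3", "H4", "H1")],
            )
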