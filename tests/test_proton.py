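import numpy as np
import pytest

from autonmr.proton import (
    Multiplet,
    PeakParams,
    PickedPeak,
    build_multiplets,
    fit_region,
    group_multiplets,
    normalize_integrals,
    pick_peaks_derivative,
    process_proton,
    prune_noise_bic,
    read_multiplet_report,
    remove_solvent_and_reference,
    solvent_score,
    write_multiplet_report,
)
from autonmr.proton import SOLVENT_TABLE
from autonmr.synthetic import MultipletSpec, SpectrumSpec
from tests.conftest import prepare


class TestPicking:
    def test_all_true_lines_found(self, processed_clean_proton):
        s3, _, truth = processed_clean_proton
        peaks = pick_peaks_derivative(s3)
        for mult_lines in truth.line_ppm:
            for line in mult_lines:
                nearest = min(abs(p.position - line) for p in peaks)
                assert nearest <= 2 * s3.ppm_per_point

    def test_requires_noise_estimate(self, processed_clean_proton):
        s3, _, _ = processed_clean_proton
        s3 = s3.copy()
        s3.noise_sigma = None
        with pytest.raises(ValueError):
            pick_peaks_derivative(s3)


class TestGrouping:
    @pytest.mark.parametrize(
        "positions,expected_groups",
        [
            ([1.000, 1.040], 1),   # 16 Hz at 400 MHz
            ([1.000, 1.100], 2),   # 40 Hz
            ([1.000], 1),
            ([1.0, 1.01, 1.02, 2.0], 2),
        ],
    )
    def test_18hz_rule(self, positions, expected_groups):
        peaks = [PickedPeak(p, 10.0, -1.0) for p in positions]
        assert len(group_multiplets(peaks, 400.0)) == expected_groups

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        positions = sorted(rng.uniform(0, 10, 20))
        peaks = [PickedPeak(p, 1.0, -1.0) for p in positions]
        ref = [[p.position for p in g] for g in group_multiplets(peaks, 400.0)]
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        alt = [[p.position for p in g] for g in group_multiplets(shuffled, 400.0)]
        assert ref == alt


class TestFitRegion:
    def test_two_overlapping_lorentzians(self, processed_clean_proton):
        s3, _, truth = processed_clean_proton
        # use the doublet at 1.05 ppm: two overlapping lines, J = 6.8 Hz
        peaks = pick_peaks_derivative(s3)
        groups = group_multiplets(peaks, s3.spectrometer_frequency)
        group = next(g for g in groups if abs(g[0].position - 1.05) < 0.1)
        model = fit_region(s3, group)
        assert model.converged
        for line in truth.line_ppm[0]:
            err_hz = min(
                abs(p.center - line) * s3.spectrometer_frequency
                for p in model.peaks
            )
            assert err_hz < 0.3

    def test_integral_matches_proton_share(self, processed_clean_proton):
        s3, _, truth = processed_clean_proton
        result = process_proton(s3)
        mults = result["multiplets"]
        ints = np.array([m.raw_integral for m in mults])
        # integrals in ratio 3:2:1:1
        scaled = ints / ints.min()
        assert np.allclose(np.sort(scaled), [1, 1, 2, 3], atol=0.15)


class TestBicPruning:
    def test_clean_region_keeps_all(self, processed_clean_proton):
        s3, _, _ = processed_clean_proton
        peaks = pick_peaks_derivative(s3)
        groups = group_multiplets(peaks, s3.spectrometer_frequency)
        group = next(g for g in groups if abs(g[0].position - 2.45) < 0.1)
        model = fit_region(s3, group)
        pruned = prune_noise_bic(model, s3)
        # the triplet keeps (at least) its three genuine lines
        assert len(pruned.peaks) >= 3

    def test_all_noise_region_emptied(self):
        spec = SpectrumSpec(
            multiplets=[MultipletSpec(5.0, "singlet", width=1.2, protons=1)],
            noise_sd=2.0, points=4096, seed=42,
        )
        s3, _, _ = prepare(spec)
        # fabricate a pick on pure noise far from the signal
        j = s3.index_of_ppm(9.0)
        fake = PickedPeak(float(s3.ppm_axis[j]), float(abs(s3.real[j]) + 1), -1.0, j)
        model = fit_region(s3, [fake])
        pruned = prune_noise_bic(model, s3)
        assert len(pruned.peaks) == 0


class TestSolvent:
    def test_quintet_beats_nearby_singlet(self):
        entry = SOLVENT_TABLE["dmso"]
        sfo = 400.0
        j_ppm = entry["j"] / sfo
        quintet = [
            PeakParams(2.52 + (k - 2) * j_ppm, a * 10.0, 1.0, 0.0)
            for k, a in enumerate(entry["pattern"])
        ]
        singlet = [PeakParams(2.49, 40.0, 1.0, 0.0)]
        score_q = solvent_score(quintet[2], quintet, entry, sfo)
        score_s = solvent_score(singlet[0], singlet, entry, sfo)
        assert score_q > score_s

    def test_removal_and_referencing(self):
        sfo = 400.0
        mults = [
            Multiplet([PeakParams(1.22, 50, 1.1, 0)], sfo),
            Multiplet([PeakParams(7.29, 90, 1.1, 0)], sfo),  # solvent, +0.03
        ]
        out, shift = remove_solvent_and_reference(mults, "chloroform")
        assert shift == pytest.approx(-0.03, abs=1e-6)
        assert len(out) == 1
        assert out[0].center == pytest.approx(1.19, abs=1e-6)

    def test_no_candidate_in_window(self):
        mults = [Multiplet([PeakParams(1.0, 50, 1.1, 0)], 400.0)]
        out, shift = remove_solvent_and_reference(mults, "chloroform")
        assert shift == 0.0 and len(out) == 1

    def test_unknown_solvent_rejected(self):
        with pytest.raises(ValueError):
            remove_solvent_and_reference([], "heavy water")


def _mults_with_integrals(integrals, sfo=400.0):
    out = []
    for i, v in enumerate(integrals):
        amp = v / (1.2 / sfo * np.pi / 2)  # height giving integral v
        out.append(Multiplet([PeakParams(1.0 + i, amp, 1.2, 0.0)], sfo))
    return out


class TestNormalizeIntegrals:
    @pytest.mark.parametrize(
        "integrals,total,labile,expected",
        [
            ([1.02, 1.51, 0.49], 6, 0, [2, 3, 1]),
            ([1.0, 2.0, 3.0], 6, 0, [1, 2, 3]),
            ([2.9, 2.1, 1.05], 7, 1, [3, 2, 1]),
        ],
    )
    def test_against_brute_force(self, integrals, total, labile, expected):
        mults = _mults_with_integrals(integrals)
        out = normalize_integrals(mults, total, labile)
        assert [m.proton_count for m in out] == expected

        # independent oracle: exhaustive search over the allowed totals
        raw = np.array(integrals)
        best_n, best_score = None, -np.inf
        for n in range(max(1, total - labile), 2 * total + 1):
            scaled = raw * n / raw.sum()
            score = np.prod(np.clip(1 - 2 * np.abs(scaled - np.round(scaled)), 0.01, None))
            if score > best_score:
                best_n, best_score = n, score
        oracle = np.round(raw * best_n / raw.sum()).astype(int).tolist()
        assert [m.proton_count for m in out] == oracle

    def test_count_sum_within_allowed_range(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = int(rng.integers(2, 7))
            counts = rng.integers(1, 4, k)
            raw = counts * rng.uniform(0.9, 1.1, k)
            total = int(counts.sum()) + 1
            out = normalize_integrals(_mults_with_integrals(raw), total, 1)
            got = sum(m.proton_count for m in out)
            assert total - 1 <= got <= 2 * total

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            normalize_integrals([], 2, 3)


class TestReports:
    def test_round_trip(self, tmp_path, processed_clean_proton):
        s3, _, _ = processed_clean_proton
        mults = process_proton(s3, total_protons=7)["multiplets"]
        for fmt, name in (("csv", "m.tsv"), ("json", "m.json")):
            path = write_multiplet_report(mults, tmp_path / name, fmt=fmt)
            back = read_multiplet_report(path)
            assert len(back) == len(mults)
            for a, b in zip(mults, back):
                assert a.center == pytest.approx(b.center)
                assert a.proton_count == b.proton_count


def test_end_to_end_proton_counts(processed_clean_proton):
    s3, _, truth = processed_clean_proton
    result = process_proton(s3, total_protons=7, labile_protons=0)
    got = sorted(
        (round(m.center, 2), m.proton_count) for m in result["multiplets"]
    )
    want = sorted(
        (round(c, 2), p)
        for c, p in zip(truth.multiplet_center, truth.proton_count)
    )
    assert got == want
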