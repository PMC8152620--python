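import numpy as np
import pytest

from autonmr.carbon import (
    CarbonPeak,
    amplitude_group_boundaries,
    group_amplitudes_and_weight,
    pick_peaks_iterative,
    process_carbon,
)
from autonmr.spectra_io import Spectrum
from autonmr.synthetic import MultipletSpec, SpectrumSpec, fixture_library
from tests.conftest import prepare


def _carbon_spec(amplitudes, noise_sd=1.0, seed=7):
    positions = np.linspace(20, 180, len(amplitudes))
    return SpectrumSpec(
        multiplets=[
            MultipletSpec(float(p), "singlet", width=1.5, amplitude=float(a))
            for p, a in zip(positions, amplitudes)
        ],
        noise_sd=noise_sd,
        nucleus="C13",
        field_mhz=100.6,
        sweep=24000.0,
        points=16384,
        offset_ppm=100.0,
        seed=seed,
    )


class TestIterativePicking:
    def test_three_amplitudes_three_peaks(self):
        # heights scale as amplitude * sweep / (pi * width); amplitude 0.04
        # with noise 12 gives the smallest peak ~10x the noise sd
        spec = _carbon_spec([0.4, 0.2, 0.04], noise_sd=12.0)
        s3, _, truth = prepare(spec)
        peaks = pick_peaks_iterative(s3)
        assert len(peaks) == 3
        for true_pos in truth.multiplet_center:
            assert min(abs(p.position - true_pos) for p in peaks) < 0.05

    def test_empty_below_stopping_rule(self):
        rng = np.random.default_rng(3)
        n = 16384
        s = Spectrum(
            rng.normal(0, 1, n) + 1j * rng.normal(0, 1, n),
            np.linspace(219, -19, n),
            nucleus="C13",
            spectrometer_frequency=100.6,
            noise_sigma=1.0,
        )
        assert pick_peaks_iterative(s) == []

    def test_quaternary_scale_peak_found(self):
        # one peak 25x weaker than the others, as a quaternary carbon is
        spec = _carbon_spec([1.0, 1.0, 0.04, 1.0], noise_sd=12.0)
        s3, _, truth = prepare(spec)
        peaks = pick_peaks_iterative(s3)
        weak_pos = truth.multiplet_center[2]
        assert any(abs(p.position - weak_pos) < 0.05 for p in peaks)

    def test_idempotent_on_own_output(self):
        spec = _carbon_spec([1.0, 0.5, 0.2], noise_sd=10.0)
        s3, _, _ = prepare(spec)
        peaks = pick_peaks_iterative(s3)
        # render the picked model as a clean spectrum and re-pick
        x = s3.ppm_axis
        y = np.zeros_like(x)
        for p in peaks:
            u = 2 * (x - p.position) / (p.width / s3.spectrometer_frequency)
            y = y + p.amplitude / (1 + u * u)
        rendered = Spectrum(
            y + 0j,
            x,
            nucleus="C13",
            spectrometer_frequency=s3.spectrometer_frequency,
            noise_sigma=s3.noise_sigma,  # fixed noise level, clean render
        )
        again = pick_peaks_iterative(rendered)
        assert len(again) == len(peaks)
        got = sorted(p.position for p in again)
        want = sorted(p.position for p in peaks)
        np.testing.assert_allclose(got, want, atol=0.05)


class TestAmplitudeWeighting:
    def test_fig_style_worked_example(self):
        rng = np.random.default_rng(5)
        amps = (
            list(1.0 + 0.05 * rng.standard_normal(10))
            + list(5.0 + 0.2 * rng.standard_normal(5))
            + list(10.0 + 0.3 * rng.standard_normal(2))
        )
        peaks = [CarbonPeak(float(i * 10), float(a)) for i, a in enumerate(amps)]
        out = group_amplitudes_and_weight(peaks, 9)
        weights = {p.amplitude_group: p.weight for p in out}
        assert weights[1] == pytest.approx(1.0)
        assert weights[2] == pytest.approx(2.0 / 7.0)
        assert weights[3] == pytest.approx(2.0 / 17.0)

    def test_all_equal_single_group(self):
        peaks = [CarbonPeak(float(i), 5.0) for i in range(8)]
        out = group_amplitudes_and_weight(peaks, 8)
        assert all(p.amplitude_group == 1 and p.weight == 1.0 for p in out)

    def test_boundary_matches_density_valley_oracle(self):
        rng = np.random.default_rng(11)
        amps = np.concatenate([
            1.0 + 0.05 * rng.standard_normal(8),
            9.0 + 0.4 * rng.standard_normal(8),
        ])
        boundaries = amplitude_group_boundaries(amps)
        assert len(boundaries) == 1
        # oracle: exhaustive valley search on the density curve
        from scipy.stats import gaussian_kde

        vals = np.log(amps)
        kde = gaussian_kde(vals, bw_method=0.25)
        grid = np.linspace(vals.min() - 1, vals.max() + 1, 2048)
        dens = kde(grid)
        interior = slice(1, -1)
        valley_idx = [
            i for i in range(1, 2047)
            if dens[i] <= dens[i - 1] and dens[i] < dens[i + 1]
        ]
        assert len(valley_idx) == 1
        assert abs(np.log(boundaries[0]) - grid[valley_idx[0]]) < 0.1

    def test_weights_in_unit_interval_and_top_group_is_one(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            amps = rng.lognormal(0, 1.5, int(rng.integers(3, 30)))
            peaks = [CarbonPeak(float(i), float(a)) for i, a in enumerate(amps)]
            out = group_amplitudes_and_weight(peaks, 12)
            ws = [p.weight for p in out]
            assert all(0 < w <= 1 for w in ws)
            top = [p for p in out if p.amplitude_group == 1]
            assert all(p.weight == 1.0 for p in top)
            ranks = sorted({p.amplitude_group for p in out})
            assert ranks == list(range(1, len(ranks) + 1))

    def test_too_few_peaks_single_group(self):
        peaks = [CarbonPeak(10.0, 5.0), CarbonPeak(20.0, 1.0)]
        out = group_amplitudes_and_weight(peaks, 4)
        assert all(p.weight == 1.0 for p in out)

    def test_bad_n_carbons(self):
        with pytest.raises(ValueError):
            group_amplitudes_and_weight([CarbonPeak(1.0, 1.0)], 0)


def test_process_carbon_on_fixture():
    spec = fixture_library()["c13_sparse"]
    s3, _, truth = prepare(spec)
    peaks = process_carbon(s3, n_carbons=5)
    assert len(peaks) >= 5
    for c in truth.multiplet_center:
        assert min(abs(p.position - c) for p in peaks) < 0.05


def test_pick_recovery_over_many_random_spectra():
    """Over 50 random 13C spectra (10-40 carbons, ~10% degenerate pairs,
    ~20% quaternary-weak peaks, SNR 5-100): >= 95% of true peaks picked
    and extra picks bounded at 10% of the true count."""
    import math

    rng = np.random.default_rng(13)
    n_true_total = n_found = n_extra = 0
    for trial in range(50):
        n_carbons = int(rng.integers(10, 41))
        n_unique = max(2, n_carbons - max(1, n_carbons // 10))
        positions = []
        while len(positions) < n_unique:
            c = float(rng.uniform(5, 195))
            if all(abs(c - o) > 1.0 for o in positions):
                positions.append(c)
        amps = {
            p: (0.25 if rng.random() < 0.2 else 1.0) * float(rng.uniform(0.8, 1.2))
            for p in positions
        }
        for p in rng.choice(positions, n_carbons - n_unique, replace=False):
            amps[float(p)] *= 2.0  # coincident carbons double the peak
        snr = float(rng.uniform(5, 100))
        h_min = min(amps.values()) * 24000.0 / (math.pi * 2.5)
        spec = SpectrumSpec(
            multiplets=[
                MultipletSpec(p, "singlet", width=1.5, amplitude=a)
                for p, a in amps.items()
            ],
            noise_sd=h_min / snr, nucleus="C13", field_mhz=100.6,
            sweep=24000.0, points=16384, offset_ppm=100.0, seed=1000 + trial,
        )
        s3, _, truth = prepare(spec)
        found = [p.position for p in pick_peaks_iterative(s3)]
        n_true_total += len(positions)
        n_found += sum(
            1 for t in truth.multiplet_center
            if any(abs(t - f) < 0.1 for f in found)
        )
        n_extra += sum(
            1 for f in found
            if not any(abs(t - f) < 0.1 for t in truth.multiplet_center)
        )
    assert n_found / n_true_total >= 0.95
    assert n_extra / n_true_total <= 0.10
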