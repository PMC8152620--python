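"""Ground-truth synthetic NMR data.

Generates raw FIDs from declarative spectrum specifications -- sums of
damped complex sinusoids arranged into first-order multiplets (binomial
line intensities), with injected zero/first-order phase error, polynomial
baseline drift, an optional solvent multiplet and Gaussian noise -- plus
the ground-truth record needed to score every downstream stage.  Also
simulates calculated-shift tables: a true candidate whose shifts are a
linear distortion of the truth plus model-distributed errors, and decoys
carrying an extra per-atom perturbation.

All randomness is driven by an explicit seed; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .spectra_io import RawFID, Spectrum, write_bruker
from .dp4 import ErrorModel

__all__ = [
    "MultipletSpec",
    "SpectrumSpec",
    "GroundTruth",
    "simulate_fid",
    "simulate_candidates",
    "fixture_library",
    "PATTERNS",
]

#: Relative line intensities for first-order patterns.
PATTERNS = {
    "singlet": [1.0],
    "doublet": [1.0, 1.0],
    "triplet": [1.0, 2.0, 1.0],
    "quartet": [1.0, 3.0, 3.0, 1.0],
    "quintet": [1.0, 4.0, 6.0, 4.0, 1.0],
}


@dataclass
class MultipletSpec:
    """One chemical environment: a first-order multiplet."""

    center: float  # ppm
    pattern: str = "singlet"
    j: float = 7.0  # Hz between adjacent lines
    amplitude: float = 1.0  # per-proton integral scale
    width: float = 1.2  # Lorentzian FWHM, Hz
    protons: int = 1


@dataclass
class SpectrumSpec:
    """Full synthetic acquisition specification."""

    multiplets: list[MultipletSpec] = field(default_factory=list)
    noise_sd: float = 0.0  # frequency-domain real-part noise sd
    phi0: float = 0.0  # radians
    phi1: float = 0.0  # radians across the sweep
    baseline_coeffs: tuple[float, ...] = ()  # polynomial in fractional position
    solvent_peak: MultipletSpec | None = None
    nucleus: str = "H1"
    solvent: str = "chloroform"
    field_mhz: float = 400.0
    points: int = 8192
    sweep: float = 4800.0
    offset_ppm: float = 6.0  # carrier position in ppm
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything needed to score the processing pipeline."""

    line_ppm: list[list[float]]  # per multiplet, per line
    line_amplitude: list[list[float]]
    multiplet_center: list[float]  # intensity-weighted mean line position
    multiplet_integral: list[float]
    proton_count: list[int]
    solvent_center: float | None
    phi0: float
    phi1: float
    noise_sd: float


def _lines(m: MultipletSpec, field_mhz: float) -> tuple[np.ndarray, np.ndarray]:
    """Line positions (ppm) and integrals of one multiplet."""
    weights = np.asarray(PATTERNS[m.pattern])
    k = weights.size
    offsets_hz = (np.arange(k) - (k - 1) / 2.0) * m.j
    ppm = m.center + offsets_hz / field_mhz
    integrals = m.amplitude * m.protons * weights / weights.sum()
    return ppm, integrals


def simulate_fid(spec: SpectrumSpec) -> tuple[RawFID, GroundTruth]:
    """Simulate a raw FID and its ground truth.

    The clean signal is built in the time domain as a sum of exponentially
    damped complex sinusoids (one per multiplet line, integral equal to the
    line's share of the proton count).  Phase error, baseline drift, the
    solvent multiplet and complex Gaussian noise are injected in the
    frequency domain, and the result is inverse transformed back to a FID
    so that the round trip through the processing pipeline faces exactly
    the artefacts real data would show.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.points
    dt = 1.0 / spec.sweep
    t = np.arange(n) * dt
    carrier_ppm = spec.offset_ppm

    def add_multiplet(sig: np.ndarray, m: MultipletSpec) -> tuple[list, list]:
        ppm, integrals = _lines(m, spec.field_mhz)
        for p, a in zip(ppm, integrals):
            f_hz = (p - carrier_ppm) * spec.field_mhz
            # time-domain amplitude a/n makes the (unapodized) discrete FT
            # carry peak integral proportional to a on the ppm axis
            sig += a * np.exp(2j * np.pi * f_hz * t - np.pi * m.width * t)
        return list(ppm), list(integrals)

    signal = np.zeros(n, dtype=complex)
    truth_pos, truth_amp, centers, integrals, protons = [], [], [], [], []
    for m in spec.multiplets:
        ppm, ints = add_multiplet(signal, m)
        truth_pos.append(ppm)
        truth_amp.append(ints)
        centers.append(float(np.average(ppm, weights=ints)))
        integrals.append(float(sum(ints)))
        protons.append(m.protons)

    solvent_center = None
    if spec.solvent_peak is not None:
        ppm, ints = add_multiplet(signal, spec.solvent_peak)
        solvent_center = float(np.average(ppm, weights=ints))

    # frequency domain: inject phase, baseline and noise
    freq = np.fft.fftshift(np.fft.fft(signal))
    m_pts = freq.size
    x = np.arange(m_pts) / m_pts
    # the spectrum is stored descending in ppm; the stored fractional
    # position of FFT bin i is therefore (1 - i/m).  Apply the phase ramp
    # in stored-axis coordinates so phi1 matches the correction convention.
    x_stored = 1.0 - x - 1.0 / m_pts
    freq = freq * np.exp(1j * (spec.phi0 + spec.phi1 * x_stored))
    if spec.baseline_coeffs:
        freq = freq + np.polyval(spec.baseline_coeffs[::-1], x_stored)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, m_pts) + 1j * rng.normal(
            0.0, spec.noise_sd, m_pts
        )
        freq = freq + noise

    fid_points = np.fft.ifft(np.fft.ifftshift(freq))
    fid = RawFID(
        points=fid_points,
        spectrometer_frequency=spec.field_mhz,
        sweep_width=spec.sweep,
        frequency_offset=carrier_ppm * spec.field_mhz,
        nucleus=spec.nucleus,
        solvent=spec.solvent,
        group_delay=0.0,
    )
    truth = GroundTruth(
        line_ppm=truth_pos,
        line_amplitude=truth_amp,
        multiplet_center=centers,
        multiplet_integral=integrals,
        proton_count=protons,
        solvent_center=solvent_center,
        phi0=spec.phi0,
        phi1=spec.phi1,
        noise_sd=spec.noise_sd,
    )
    return fid, truth


def write_fixture(spec: SpectrumSpec, directory: str | Path, **bruker_kwargs) -> Path:
    """Write a Bruker-dialect fixture directory plus a JSON truth file."""
    directory = Path(directory)
    fid, truth = simulate_fid(spec)
    write_bruker(fid, directory, **bruker_kwargs)
    (directory / "truth.json").write_text(json.dumps(asdict(truth), indent=1))
    return directory


# ---------------------------------------------------------------------------
# Calculated-shift simulation
# ---------------------------------------------------------------------------

def simulate_candidates(
    true_shifts: np.ndarray,
    n_decoys: int,
    decoy_perturbation: float,
    error_model: ErrorModel,
    scaling: tuple[float, float] = (1.0, 0.0),
    seed: int = 0,
    labels: list[str] | None = None,
):
    """Simulate per-candidate calculated-shift tables.

    The true candidate's shifts are ``slope * shift + intercept`` plus
    draws from ``error_model``; each decoy additionally receives a
    per-atom Gaussian perturbation of sd ``decoy_perturbation`` ppm.

    Returns ``(tables, true_index)`` where each table is a list of
    ``(atom_label, calculated_shift)`` pairs and ``true_index`` names the
    candidate generated without extra perturbation.
    """
    rng = np.random.default_rng(seed)
    true_shifts = np.asarray(true_shifts, dtype=float)
    n = true_shifts.size
    if labels is None:
        labels = [f"C{i + 1}" for i in range(n)]
    slope, intercept = scaling

    def draw_errors() -> np.ndarray:
        comp = rng.choice(
            len(error_model.components),
            size=n,
            p=[c[2] for c in error_model.components],
        )
        means = np.array([error_model.components[c][0] for c in comp])
        sds = np.array([error_model.components[c][1] for c in comp])
        return rng.normal(means, sds)

    candidates = []
    order = rng.permutation(n_decoys + 1)
    true_index = int(np.flatnonzero(order == 0)[0])
    for slot in order:
        shifts = slope * true_shifts + intercept + draw_errors()
        if slot != 0:
            shifts = shifts + rng.normal(0.0, decoy_perturbation, n)
        candidates.append(list(zip(labels, shifts.tolist())))
    return candidates, true_index


# ---------------------------------------------------------------------------
# Named fixture library
# ---------------------------------------------------------------------------

def fixture_library() -> dict[str, SpectrumSpec]:
    """Twelve named specifications spanning the conditions the pipeline faces.

    Proton cases cover clean, noisy, overlapped and solvent-contaminated
    spectra; carbon cases cover sparse, crowded and degenerate peak sets
    with quaternary-carbon-like weak signals.
    """
    M = MultipletSpec
    lib: dict[str, SpectrumSpec] = {}
    lib["h1_clean"] = SpectrumSpec(
        multiplets=[
            M(1.05, "doublet", 6.8, width=1.0, protons=3),
            M(2.45, "triplet", 7.2, width=1.2, protons=2),
            M(4.10, "quartet", 7.0, width=1.2, protons=1),
            M(7.35, "singlet", width=1.0, protons=1),
        ],
        noise_sd=0.8,
        seed=11,
    )
    lib["h1_noisy"] = SpectrumSpec(
        multiplets=[
            M(0.95, "triplet", 7.0, width=1.4, protons=3),
            M(1.60, "singlet", width=1.6, protons=2),
            M(3.70, "doublet", 6.5, width=1.4, protons=2),
            M(6.90, "doublet", 8.0, width=1.4, protons=1),
        ],
        noise_sd=20.0,
        phi0=math.radians(25.0),
        phi1=math.radians(40.0),
        baseline_coeffs=(0.05, -0.1, 0.08),
        seed=12,
    )
    lib["h1_overlapped"] = SpectrumSpec(
        multiplets=[
            M(2.30, "triplet", 7.4, width=1.6, protons=2),
            M(2.36, "doublet", 7.0, width=1.6, protons=2),
            M(5.20, "singlet", width=1.2, protons=1),
        ],
        noise_sd=2.0,
        seed=13,
    )
    lib["h1_solvent"] = SpectrumSpec(
        multiplets=[
            M(1.25, "doublet", 6.9, width=1.1, protons=3),
            M(3.45, "quartet", 6.9, width=1.2, protons=1),
            M(6.10, "singlet", width=1.0, protons=1),
        ],
        solvent_peak=M(7.29, "singlet", width=1.1, amplitude=2.5, protons=1),
        noise_sd=1.0,
        seed=14,
    )
    lib["h1_phase_stress"] = SpectrumSpec(
        multiplets=[
            M(0.90, "triplet", 7.1, width=1.2, protons=3),
            M(1.55, "singlet", width=1.4, protons=3),
            M(2.20, "doublet", 7.6, width=1.2, protons=2),
            M(3.95, "triplet", 6.4, width=1.2, protons=2),
            M(5.45, "singlet", width=1.0, protons=1),
            M(7.60, "doublet", 8.2, width=1.2, protons=1),
        ],
        noise_sd=3.0,
        phi0=math.radians(-60.0),
        phi1=math.radians(70.0),
        seed=15,
    )
    lib["h1_labile"] = SpectrumSpec(
        multiplets=[
            M(1.15, "doublet", 6.6, width=1.1, protons=3),
            M(2.65, "singlet", width=1.3, protons=2),
            M(4.35, "singlet", width=1.6, protons=1),
        ],
        noise_sd=2.0,
        seed=16,
    )
    lib["h1_dense"] = SpectrumSpec(
        multiplets=[
            M(0.88, "triplet", 7.0, width=1.1, protons=3),
            M(1.30, "singlet", width=1.5, protons=6),
            M(1.95, "quintet", 6.8, width=1.4, protons=2),
            M(2.55, "triplet", 7.3, width=1.3, protons=2),
            M(3.60, "singlet", width=1.2, protons=3),
            M(5.30, "triplet", 6.2, width=1.2, protons=1),
            M(7.20, "doublet", 8.0, width=1.2, protons=2),
            M(7.75, "doublet", 8.0, width=1.2, protons=2),
        ],
        noise_sd=2.0,
        phi0=math.radians(15.0),
        seed=17,
    )
    lib["h1_weak"] = SpectrumSpec(
        multiplets=[
            M(1.40, "doublet", 6.7, width=1.3, protons=3),
            M(3.10, "singlet", width=1.4, protons=1),
        ],
        noise_sd=25.0,
        seed=18,
    )
    c_sweep = dict(
        nucleus="C13",
        field_mhz=100.6,
        sweep=24000.0,
        points=16384,
        offset_ppm=100.0,
    )
    lib["c13_sparse"] = SpectrumSpec(
        multiplets=[
            M(14.1, width=1.5, amplitude=1.0),
            M(22.7, width=1.5, amplitude=1.1),
            M(77.2, width=1.5, amplitude=0.9),
            M(128.4, width=1.5, amplitude=1.0),
            M(171.0, width=1.5, amplitude=0.35),  # quaternary-like
        ],
        noise_sd=30.0,
        seed=21,
        **c_sweep,
    )
    lib["c13_crowded"] = SpectrumSpec(
        multiplets=[
            M(p, width=1.6, amplitude=a)
            for p, a in [
                (11.9, 1.0), (18.3, 1.05), (24.6, 0.95), (29.0, 1.0),
                (33.8, 1.1), (41.2, 0.9), (56.4, 1.0), (68.9, 0.95),
                (98.7, 0.3), (112.5, 1.0), (126.8, 2.0), (129.3, 1.9),
                (137.2, 0.35), (152.9, 0.3), (168.4, 0.32),
            ]
        ],
        noise_sd=30.0,
        seed=22,
        **c_sweep,
    )
    lib["c13_degenerate"] = SpectrumSpec(
        multiplets=[
            M(21.5, width=1.5, amplitude=2.0),  # two coincident carbons
            M(35.2, width=1.5, amplitude=1.0),
            M(127.5, width=1.5, amplitude=2.1),
            (M(130.1, width=1.5, amplitude=1.0)),
            M(165.3, width=1.5, amplitude=0.4),
        ],
        noise_sd=30.0,
        seed=23,
        **c_sweep,
    )
    lib["c13_noisy"] = SpectrumSpec(
        multiplets=[
            M(25.9, width=1.8, amplitude=1.0),
            M(48.2, width=1.8, amplitude=0.9),
            M(75.6, width=1.8, amplitude=0.4),
            M(119.8, width=1.8, amplitude=1.0),
            M(143.5, width=1.8, amplitude=0.45),
        ],
        noise_sd=100.0,
        seed=24,
        **c_sweep,
    )
    return lib
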