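"""Noise estimation, automatic phase correction and baseline removal.

Phasing follows a hybrid scheme: signal-containing regions are located
by thresholding against the noise level (signal classification); each
region's phase is measured from the complex integral over a window
symmetric about its dominant multiplet and refined by a shared-phase
complex-lineshape fit; a robust weighted linear regression of region
phase against region position yields the zero- and first-order pair;
and an entropy objective of the ACME family (entropy of the normalised
absolute derivative of the real part plus a penalty on negative
intensity) gives the final local polish, accepted only when it lowers
the objective.  The first-order phase is linear in fractional position
across the stored (descending-ppm) spectrum, zero at the first point.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .spectra_io import Spectrum

__all__ = [
    "PhaseParams",
    "SignalRegions",
    "estimate_noise",
    "classify_signal_regions",
    "acme_entropy",
    "phase_correct",
    "apply_phase",
    "baseline_correct",
]

logger = logging.getLogger(__name__)


@dataclass
class PhaseParams:
    """Zero- and first-order phase in radians.

    ``phi1`` is the total first-order phase accrued across the full sweep;
    the phase applied at fractional position ``x`` in [0, 1) is
    ``phi0 + phi1 * x``.  ``phi0`` is reported wrapped to (-pi, pi].
    """

    phi0: float
    phi1: float
    converged: bool = True
    entropy_start: float | None = None  # objective at the regression seed
    entropy_final: float | None = None  # objective after refinement

    def wrapped(self) -> "PhaseParams":
        phi0 = _wrap(self.phi0)
        return PhaseParams(
            phi0, self.phi1, self.converged, self.entropy_start, self.entropy_final
        )


def _wrap(phi: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    w = (phi + np.pi) % (2 * np.pi) - np.pi
    return float(np.pi if np.isclose(w, -np.pi) else w)


@dataclass
class SignalRegions:
    """Disjoint, sorted half-open index intervals classified as signal."""

    intervals: list[tuple[int, int]]
    n_points: int

    def __post_init__(self) -> None:
        for (a, b), nxt in zip(self.intervals, self.intervals[1:] + [None]):
            if not (0 <= a < b <= self.n_points):
                raise ValueError(f"interval ({a}, {b}) out of bounds")
            if nxt is not None and b > nxt[0]:
                raise ValueError("intervals overlap or are unsorted")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_points, dtype=bool)
        for a, b in self.intervals:
            m[a:b] = True
        return m


def estimate_noise(spectrum: Spectrum, threshold: float = 4.0) -> float:
    """Robust noise standard deviation of the real part.

    Starts from the median-absolute-deviation estimate, classifies signal
    regions against it, and re-estimates from the noise-only complement
    (two refinement passes).  Stores the result on ``spectrum.noise_sigma``.
    """
    real = spectrum.real
    if real.size < 2:
        return 0.0
    sigma = float(np.median(np.abs(real - np.median(real))) / 0.6745)
    if sigma == 0.0:
        spectrum.noise_sigma = 0.0
        return 0.0
    for _ in range(2):
        regions = classify_signal_regions(spectrum, sigma, threshold=threshold)
        noise_mask = ~regions.mask()
        if noise_mask.sum() < 32:
            warnings.warn(
                "no noise region found; falling back to whole-spectrum MAD",
                stacklevel=2,
            )
            break
        vals = real[noise_mask]
        sigma = float(np.median(np.abs(vals - np.median(vals))) / 0.6745)
        if sigma == 0.0:
            break
    spectrum.noise_sigma = sigma
    return sigma


def classify_signal_regions(
    spectrum: Spectrum,
    noise_sigma: float,
    threshold: float = 4.0,
    merge_gap_ppm: float | None = None,
    pad_points: int = 3,
    tail_fraction: float = 0.02,
) -> SignalRegions:
    """Contiguous runs whose magnitude exceeds ``threshold * noise_sigma``.

    Runs closer than ``merge_gap_ppm`` (default 0.02 ppm for proton,
    0.2 ppm for carbon) are merged, and each run is padded by a few
    points so peak tails stay inside their region.

    At high signal-to-noise the slowly decaying wings of the complex
    lineshape stay above any fixed noise multiple for a long way, which
    would classify most of the spectrum as signal.  Each run is
    therefore trimmed from its edges while the magnitude stays below
    ``tail_fraction`` of the run's own maximum, keeping regions compact
    independently of peak height.
    """
    if noise_sigma <= 0:
        raise ValueError("noise_sigma must be positive")
    if merge_gap_ppm is None:
        merge_gap_ppm = 0.02 if spectrum.nucleus == "H1" else 0.2
    gap_pts = max(1, int(round(merge_gap_ppm / spectrum.ppm_per_point)))

    mag = np.abs(spectrum.intensity)
    n = spectrum.n_points
    base_cut = threshold * noise_sigma

    def runs_above(lo: int, hi: int, cutoff: float) -> list[tuple[int, int]]:
        idx = lo + np.flatnonzero(mag[lo:hi] > cutoff)
        if idx.size == 0:
            return []
        breaks = np.flatnonzero(np.diff(idx) > gap_pts)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]

    # recursively re-threshold each run at a fraction of its own maximum,
    # splitting runs that were only bridged by the wings of taller peaks
    final: list[tuple[int, int]] = []
    stack = runs_above(0, n, base_cut)
    while stack:
        a, b = stack.pop()
        cutoff = max(base_cut, tail_fraction * float(mag[a:b].max()))
        if cutoff <= base_cut * (1 + 1e-9):
            final.append((a, b))
            continue
        sub = runs_above(a, b, cutoff)
        if len(sub) == 1 and sub[0] == (a, b):
            final.append((a, b))
        else:
            stack.extend(sub)

    final.sort()
    intervals: list[list[int]] = []
    for a, b in final:
        a = max(0, a - pad_points)
        b = min(n, b + pad_points)
        if intervals and a <= intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], b)
        else:
            intervals.append([a, b])
    return SignalRegions([(a, b) for a, b in intervals], n)


# ---------------------------------------------------------------------------
# ACME-style entropy objective and hybrid phasing
# ---------------------------------------------------------------------------

def apply_phase(intensity: np.ndarray, phi0: float, phi1: float) -> np.ndarray:
    """Apply a zero/first-order phase rotation to a complex trace."""
    x = np.arange(intensity.size) / intensity.size
    return intensity * np.exp(-1j * (phi0 + phi1 * x))


def acme_entropy(
    real: np.ndarray,
    penalty_coefficient: float = 1000.0,
) -> float:
    """Entropy of the normalised |first derivative| plus a negativity penalty.

    Lower is better: a correctly phased absorption spectrum concentrates
    its derivative at sharp peak flanks (low entropy) and has no large
    negative excursions.
    """
    deriv = np.abs(np.diff(real))
    total = deriv.sum()
    if total == 0:
        return 0.0
    h = deriv / total
    nz = h > 0
    entropy = float(-np.sum(h[nz] * np.log(h[nz])))
    power = float(np.sum(real**2))
    if power == 0:
        return entropy
    neg = real[real < 0]
    # the penalty must dominate the entropy term: a slightly dispersive
    # line can have a *lower* derivative entropy than pure absorption
    penalty = penalty_coefficient * float(np.sum(neg**2)) / power
    return entropy + penalty


def _region_phase(
    data: np.ndarray,
    a: int,
    b: int,
    pad_points: int = 8,
    gap_points: int = 16,
) -> tuple[float, float, float, tuple[int, int]]:
    """Phase of one signal region from its complex integral.

    The segment is summed over a tight window symmetric about the
    region's dominant multiplet: the dispersion-mode contribution of a
    symmetric multiplet integrates to zero over a symmetric window, so
    the angle of the complex integral is the local phase error.  The
    window is kept as tight as the multiplet allows because the
    dispersion tails of *neighbouring* signals do not cancel and their
    integrated contribution grows with window length.

    Returns (phase, |integral| as a weight, centre fractional position,
    window index bounds).
    """
    mag = np.abs(data[a:b])
    # a region may hold several multiplets whose dispersion components do
    # not cancel jointly; centre the window on the dominant one only
    j = int(np.argmax(mag))
    cutoff = 0.2 * float(mag[j])
    gap = max(gap_points, 4)

    def walk(idx: int, step: int) -> int:
        while True:
            nxt = idx + step
            if not (0 <= nxt < mag.size):
                return idx
            if mag[nxt] > cutoff:
                idx = nxt
                continue
            # bridge short dips so the whole multiplet stays in the window
            probe = [
                idx + step * k
                for k in range(2, gap + 1)
                if 0 <= idx + step * k < mag.size
            ]
            jump = next((p for p in probe if mag[p] > cutoff), None)
            if jump is None:
                return idx
            idx = jump

    l, r = walk(j, -1), walk(j, +1) + 1
    center = a + float(np.average(np.arange(l, r), weights=mag[l:r]))
    half = (r - l) / 2.0 + pad_points
    lo = int(max(0, math.floor(center - half)))
    hi = int(min(data.size, math.ceil(center + half) + 1))
    # keep the window symmetric even at the spectrum edge
    room = min(center - lo, hi - 1 - center)
    lo = int(math.floor(center - room))
    hi = int(math.ceil(center + room)) + 1
    s = complex(np.sum(data[lo:hi]))
    # the complex-lineshape refinement benefits from a wider window (more
    # noise averaging in the wings); the integral phase must stay tight
    fhalf = half + 3 * pad_points
    flo = int(max(0, math.floor(center - fhalf)))
    fhi = int(min(data.size, math.ceil(center + fhalf) + 1))
    return float(np.angle(s)), float(abs(s)), center / data.size, (flo, fhi)


def _fit_window_phase(window: np.ndarray, phase0: float, max_lines: int = 6) -> float:
    """Refine a window's phase by a complex-Lorentzian fit.

    The window is modelled as ``exp(i*phase) * sum_k a_k / (1 + i u_k)``
    with ``u_k = 2 (x - c_k) / w_k``: every line shares one phase.  Unlike
    the integral phase, this stays unbiased when the window holds an
    asymmetric cluster of overlapping lines.  Falls back to the seed if
    the fit fails or moves implausibly far.
    """
    from scipy.optimize import least_squares
    from scipy.signal import argrelmax

    n = window.size
    if n < 8:
        return phase0
    mag = np.abs(window)
    floor = 0.15 * float(mag.max())
    peaks = [int(i) for i in argrelmax(mag, order=2)[0] if mag[i] > floor]
    if not peaks:
        peaks = [int(np.argmax(mag))]
    peaks = sorted(peaks, key=lambda i: -mag[i])[:max_lines]

    x = np.arange(n, dtype=float)
    theta0 = [phase0]
    lb, ub = [phase0 - np.pi], [phase0 + np.pi]
    for i in peaks:
        theta0 += [float(i), float(mag[i]), 3.0]
        lb += [0.0, 0.0, 1.0]
        ub += [float(n - 1), 4.0 * float(mag.max()), float(n)]

    def make_resid(sign: float):
        def resid(theta: np.ndarray) -> np.ndarray:
            model = np.zeros(n, dtype=complex)
            for k in range(len(peaks)):
                c, a_k, w = theta[1 + 3 * k : 4 + 3 * k]
                u = 2.0 * (x - c) / w
                model += a_k / (1.0 + sign * 1j * u)
            model *= np.exp(1j * theta[0])
            d = model - window
            return np.concatenate([d.real, d.imag])

        return resid

    # the dispersion sign depends on the stored axis direction; fit both
    # and keep the better model
    best_phase, best_cost = phase0, np.inf
    for sign in (-1.0, 1.0):
        try:
            sol = least_squares(
                make_resid(sign), np.clip(theta0, lb, ub), bounds=(lb, ub),
                method="trf", max_nfev=120, ftol=1e-8, xtol=1e-8,
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost, best_phase = float(sol.cost), float(sol.x[0])
    phase = best_phase
    return phase if abs(phase - phase0) < np.radians(60.0) else phase0


def _weighted_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares line y = b0 + b1 x; returns (b0, b1)."""
    W = w / w.sum()
    xm = float(np.sum(W * x))
    ym = float(np.sum(W * y))
    var = float(np.sum(W * (x - xm) ** 2))
    if var < 1e-12:
        return ym, 0.0
    slope = float(np.sum(W * (x - xm) * (y - ym)) / var)
    return ym - slope * xm, slope


def phase_correct(
    spectrum: Spectrum,
    regions: SignalRegions | None = None,
    penalty_coefficient: float = 1000.0,
) -> tuple[Spectrum, PhaseParams]:
    """Hybrid automatic phase correction.

    Stage 1 finds a per-region phase by entropy minimisation; stage 2
    fits phase against region position by weighted linear regression
    (region height times inverse entropy residual as weights, residuals
    beyond 3 MAD zero-weighted); stage 3 refines the pair with a global
    entropy minimisation over the signal regions, keeping the regression
    solution whenever refinement fails to improve the objective.
    """
    if regions is None:
        sigma = spectrum.noise_sigma or estimate_noise(spectrum)
        if sigma > 0:
            regions = classify_signal_regions(spectrum, sigma)
        else:
            regions = SignalRegions([], spectrum.n_points)
    if len(regions) == 0:
        return spectrum.copy(), PhaseParams(0.0, 0.0)

    n = spectrum.n_points
    data = spectrum.intensity
    edge = max(4, int(0.01 * n))  # spectrum ends carry filter/wrap artifacts
    hz_per_point = spectrum.hz_per_point
    pad_pts = max(4, int(round(4.0 / hz_per_point)))
    gap_pts = max(4, int(round(18.0 / hz_per_point)))
    centers, phases, weights, windows = [], [], [], []
    for a, b in regions:
        if a < edge or b > n - edge:
            continue
        phi, weight, x_c, win = _region_phase(
            data, a, b, pad_points=pad_pts, gap_points=gap_pts
        )
        centers.append(x_c)
        phases.append(phi)
        weights.append(weight)
        windows.append(win)
    if not centers:
        return spectrum.copy(), PhaseParams(0.0, 0.0)
    centers = np.asarray(centers)
    phases = np.asarray(phases)
    weights = np.asarray(weights)

    # weak (mostly noise) regions would only dilute the regression, and a
    # fragment of a strong peak's dispersion wing classifies as its own
    # "region" with a ~90-degree phase; drop both kinds when enough
    # strong regions remain
    sweep_hz = abs(spectrum.ppm_axis[0] - spectrum.ppm_axis[-1]) * (
        spectrum.spectrometer_frequency
    )
    keep_idx = []
    for i in range(centers.size):
        if weights[i] <= 0.2 * weights.max():
            continue
        is_wing = any(
            j != i
            and weights[j] > 5.0 * weights[i]
            and abs(centers[i] - centers[j]) * sweep_hz < 60.0
            for j in range(centers.size)
        )
        if not is_wing:
            keep_idx.append(i)
    if len(keep_idx) >= 2:
        strong = np.asarray(keep_idx)
        centers = centers[strong]
        phases = phases[strong]
        weights = weights[strong]
        windows = [windows[i] for i in strong]
    for idx in sorted(range(len(windows)), key=lambda i: -weights[i])[:12]:
        lo, hi = windows[idx]
        phases[idx] = _fit_window_phase(data[lo:hi], float(phases[idx]))

    # unwrap phases along the spectrum, anchored at the strongest region:
    # adjacent regions should differ by much less than a full turn when
    # |phi1| is moderate
    order = np.argsort(centers)
    anchor_pos = int(np.flatnonzero(order == int(np.argmax(weights)))[0])
    unwrapped = phases.copy()
    for pos in range(anchor_pos + 1, len(order)):
        prev, cur = order[pos - 1], order[pos]
        delta = unwrapped[cur] - unwrapped[prev]
        unwrapped[cur] -= 2 * np.pi * np.round(delta / (2 * np.pi))
    for pos in range(anchor_pos - 1, -1, -1):
        prev, cur = order[pos + 1], order[pos]
        delta = unwrapped[cur] - unwrapped[prev]
        unwrapped[cur] -= 2 * np.pi * np.round(delta / (2 * np.pi))

    def wlr(w: np.ndarray) -> tuple[float, float]:
        if centers.size >= 2 and np.sum(w > 0) >= 2:
            return _weighted_fit(centers, unwrapped, w)
        j = int(np.argmax(w))
        return float(unwrapped[j]), 0.0

    # robustness: weighted Theil-Sen start, then iteratively reweighted
    # least squares (Tukey biweight).  Regions holding overlapped,
    # asymmetric multiplets carry phase biases of tens of degrees; they
    # can be strong, so the redescending fit must start from a
    # high-breakdown estimate rather than from the raw weighted fit.
    phi0, phi1 = wlr(weights)
    if centers.size >= 3:
        slopes, sw = [], []
        for i in range(centers.size):
            for j in range(i + 1, centers.size):
                dx = centers[j] - centers[i]
                if abs(dx) < 0.1:
                    continue
                slopes.append((unwrapped[j] - unwrapped[i]) / dx)
                sw.append(min(weights[i], weights[j]))
        if slopes:
            slopes = np.asarray(slopes)
            sw = np.asarray(sw)
            order_s = np.argsort(slopes)
            cum = np.cumsum(sw[order_s])
            phi1 = float(slopes[order_s][np.searchsorted(cum, 0.5 * cum[-1])])
            inter = unwrapped - phi1 * centers
            order_i = np.argsort(inter)
            cum = np.cumsum(weights[order_i])
            phi0 = float(inter[order_i][np.searchsorted(cum, 0.5 * cum[-1])])
    for _ in range(5):
        resid = unwrapped - (phi0 + phi1 * centers)
        scale = max(1.4826 * float(np.median(np.abs(resid - np.median(resid)))),
                    np.radians(1.0))
        c = 4.685 * scale
        u = np.clip(np.abs(resid - np.median(resid)) / c, 0.0, 1.0)
        w2 = weights * (1.0 - u**2) ** 2
        if np.sum(w2 > 0) < 2:
            break
        phi0, phi1 = wlr(w2)

    # stage 3: local entropy refinement around the regression solution.
    # The seed from the integral phases is already accurate; the entropy
    # objective polishes it but is only trusted inside a small box.
    mask = regions.mask()

    def objective(p: np.ndarray) -> float:
        corrected = apply_phase(data, p[0], p[1])
        return acme_entropy(corrected.real[mask], penalty_coefficient)

    seed = np.array([phi0, phi1])
    start_val = objective(seed)
    # the regression seed is already accurate to a degree or two; the
    # entropy objective is allowed a final polish only within a tight box
    box = np.radians(1.0)
    result = minimize(
        objective,
        seed,
        method="Powell",
        bounds=[(phi0 - box, phi0 + box), (phi1 - 2 * box, phi1 + 2 * box)],
        options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": 200},
    )
    converged = bool(result.success)
    if not converged:
        logger.warning("global phase refinement did not converge; using best iterate")
    final_val = start_val
    if result.fun <= start_val:
        phi0, phi1 = float(result.x[0]), float(result.x[1])
        final_val = float(result.fun)

    corrected = spectrum.copy()
    corrected.intensity = apply_phase(data, phi0, phi1)
    # sign convention: a phased spectrum should integrate positive
    if corrected.real[mask].sum() < 0:
        corrected.intensity = -corrected.intensity
        phi0 += np.pi
    return corrected, PhaseParams(
        phi0, phi1, converged, float(start_val), float(final_val)
    ).wrapped()


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def baseline_correct(
    spectrum: Spectrum,
    regions: SignalRegions | None = None,
    window_points: int | None = None,
) -> Spectrum:
    """Subtract a smooth baseline modelled through noise-classified points.

    Noise points (the complement of the signal regions) are binned into
    windows of ``window_points``; a cubic spline through the window
    medians is evaluated over the full axis and subtracted from the real
    part.  Signal regions are bridged by the spline.
    """
    from scipy.interpolate import CubicSpline

    if window_points is None:
        # carbon spectra are sparse: longer windows average the knots
        # harder and keep spline undulations below the weak-peak scale
        window_points = 64 if spectrum.nucleus == "H1" else 256
    if regions is None:
        sigma = spectrum.noise_sigma or estimate_noise(spectrum)
        if sigma > 0:
            regions = classify_signal_regions(spectrum, sigma)
        else:
            regions = SignalRegions([], spectrum.n_points)

    real = spectrum.real
    n = real.size
    noise_mask = ~regions.mask()
    idx = np.flatnonzero(noise_mask)
    if idx.size < 8:
        logger.warning("baseline correction skipped: almost no noise points")
        return spectrum.copy()

    knots_x, knots_y = [], []
    for start in range(0, n, window_points):
        sel = idx[(idx >= start) & (idx < start + window_points)]
        if sel.size >= max(4, window_points // 8):
            knots_x.append(float(sel.mean()))
            knots_y.append(float(np.median(real[sel])))
    if len(knots_x) < 4:
        baseline = np.full(n, float(np.median(real[idx])))
    else:
        spline = CubicSpline(knots_x, knots_y, bc_type="natural")
        baseline = spline(np.arange(n))
        # never extrapolate wildly past the outermost knots
        baseline[: int(knots_x[0])] = knots_y[0]
        baseline[int(knots_x[-1]) :] = knots_y[-1]

    out = spectrum.copy()
    out.intensity = spectrum.intensity - baseline
    return out
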