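# Methods

This note records the models, algorithms and numerical choices behind
`autonmr`, and what the synthetic test bed does and does not establish
about real data.

## Data model

A free induction decay (FID) is modelled as a sum of exponentially
damped complex sinusoids; its Fourier transform is a sum of complex
Lorentzians over a descending ppm axis.  Default apodization is 0.3 Hz
(¹H) / 1.0 Hz (¹³C) exponential line broadening with zero filling to
twice the next power of two; all configurable.  The digital-filter group
delay is removed by a circular left shift of the time-domain data, which
is correct to one point.  Only one acquisition-directory dialect is
supported (sweep width, carrier offset, spectrometer frequency, point
count, byte order, data type, group delay) and anything else is rejected
explicitly; JCAMP-DX support is AFFN-only, with ASDF compression
rejected rather than misread.

## Noise and signal classification

The noise standard deviation is the median absolute deviation (scaled)
of the real part over points not classified as signal, iterated twice
from a whole-spectrum MAD start.  Signal regions are runs of magnitude
above 4σ, merged across gaps of 0.02 ppm (¹H) / 0.2 ppm (¹³C).  Because
the magnitude of a complex Lorentzian decays only as 1/Δ, at realistic
signal-to-noise the wings of strong peaks stay above any fixed noise
multiple across much of the sweep; each run is therefore re-thresholded
recursively at 2% of its own maximum, which keeps regions compact
independently of peak height and splits runs bridged only by wings.

## Automatic phasing

The corrected trace is `S(x)·exp(−i(φ0 + φ1·x))` with `x` the
fractional position across the stored spectrum (0 at the first, most
downfield point) and φ1 the total first-order phase across the sweep.
Three stages:

1. **Per-region phase.**  The angle of the complex integral over a
   window symmetric about the region's dominant multiplet.  For a
   symmetric multiplet the dispersion-mode contribution integrates to
   zero over a symmetric window, so this angle is the local phase.  The
   estimate is then refined by fitting the window as
   `exp(iφ)·Σ aₖ/(1 + i uₖ)` — complex Lorentzians sharing one phase —
   which stays unbiased for asymmetric clusters of overlapping lines
   (both dispersion-sign conventions are tried; the better fit wins).
   An entropy objective was evaluated for this stage and rejected: over
   a compact region the derivative-entropy surface is nearly flat in
   phase and its minimum sits several degrees into dispersion.
   Wing fragments of strong peaks (within 60 Hz of a ≥5× stronger
   region) and weak regions (≤20% of the strongest integral) are
   excluded — their phases are dispersion-dominated artefacts.
2. **Weighted linear regression.**  Region phase against region
   position, weighted by integral magnitude, initialised by a weighted
   Theil–Sen fit and polished by iteratively reweighted least squares
   with Tukey biweights, so regions biased by peak overlap are
   rejected.  Phases are unwrapped along the sweep anchored at the
   strongest region.
3. **Entropy polish.**  The ACME-family objective — entropy of the
   normalised |first derivative| of the real part plus a penalty
   `1000·Σ(neg²)/Σ(real²)` on negative intensity — is minimised over the
   signal regions within a ±1° (φ0) / ±2° (φ1) box around the
   regression solution, and the step is accepted only if the objective
   decreases.  The penalty must dominate the entropy term because a
   slightly dispersive line can have *lower* derivative entropy than
   pure absorption.

Identifiability: with signals confined to the middle of the sweep, φ0
and φ1 trade off along the valley `φ0 ≈ −x̄·φ1` with almost no change to
the spectrum; separate 5°-level recovery of both parameters requires
signals near both sweep ends, which real proton spectra (upfield methyls
to downfield aromatics/aldehydes) provide and the synthetic families
reproduce.

## Baseline

A cubic spline through windowed medians of noise-classified points
(64-point windows for ¹H, 256 for ¹³C — carbon spectra are sparse enough
that harder averaging is free, and spline undulations must stay below
the quaternary-carbon scale), clamped at the outermost knots, subtracted
from the real part.

## Proton pipeline

* **Picking**: zero crossings of the Savitzky–Golay first derivative
  coinciding (within one grid point) with minima of the second
  derivative, kept when height > 5σ and curvature < −2σ(d²).
  Thresholds are deliberately permissive; later model selection removes
  noise picks.
* **Grouping**: single linkage, peaks < 18 Hz apart — the largest
  ¹H–¹H scalar coupling expected — share a multiplet.
* **Deconvolution**: one generalized Lorentzian per picked peak,
  `a·[(1−m)/(1+u²) + m·exp(−ln2·u²)]` with `u = 2(x−c)/w`, a
  height-normalised Lorentzian–Gaussian mixture (`m∈[0,1]`).  Bounded
  least squares over the group's region (12 Hz margins); the fit is
  repeated, adding a component at the largest positive residual, until
  the closed-form model integral matches the region integral within 1%.
  A component is only added where the residual exceeds 3σ — chasing the
  1% criterion into the noise floor would spawn spurious components,
  and with noise present the criterion is then sometimes unattainable;
  the model is flagged and processing continues.
* **BIC pruning**: each component is removed in turn and the rest
  refitted; deletion is permanent when it lowers
  `BIC = n·ln(RSS/n) + 4p·ln(n)` by more than 5.  The sample includes
  the region, a 30 Hz signal-free flank, and (analytically, as
  `n_extra·σ²` of residual) every signal-free point of the spectrum:
  the model claims zero intensity there, and referencing the parameter
  penalty to that stable sample size puts the deletion boundary
  (~30σ² of explained energy) cleanly between a noise spike (~10–15σ²)
  and the weakest genuine peak at SNR 8 (~250σ²).  A threshold of 10
  with region-only samples was tested and deletes almost nothing: the
  penalty `4·ln n` is then only ~15–20 while a 3σ spike frees ~10.
* **Solvent**: every fitted peak within ±0.5 ppm of the expected
  residual-solvent shift (chloroform 7.26, benzene 7.16, methanol 3.31,
  DMSO 2.50 ppm; quintet patterns for the latter two) is scored by how
  well the surrounding peak positions and amplitudes match the expected
  multiplet, times a Gaussian falloff in distance from the literature
  shift.  The best-scoring multiplet (above 0.2) is removed and the
  axis shifted so it would sit exactly at the reference value.
* **Integral normalisation**: candidate proton totals n run from
  (protons − labile protons) to 2×protons; integrals rescaled to sum to
  n are scored by ∏ max(0.01, 1 − 2|xᵢ − round(xᵢ)|), ties toward
  smaller n; counts round to the nearest integer and zero-count
  multiplets are dropped.  Labile protons are those bonded to O, N or S
  in the structure file.

## Carbon pipeline

Greedy deconvolution: the residual (spectrum − model) is matched-
filtered with the expected Lorentzian; the filtered maximum seeds a
local Lorentzian fit, the component joins the model, and the loop stops
when the filtered maximum drops below 3× the filtered trace's own noise
level (zero filling correlates bins, so the analytic white-noise scale
would understate it).  Guards: a few linewidths around every fitted
centre are never re-picked (residual dispersion leakage), a candidate is
only accepted when its filtered score reaches 4.5 (a correlated-noise
bump cannot), and fits that saturate the width bound (4× the expected
linewidth) are rejected as baseline undulations.  Raw-amplitude
thresholding cannot meet both requirements at once — a 4σ quaternary
carbon must be picked while 4σ noise maxima (routine over 32k points)
must not — which is exactly what matched filtering resolves.

Amplitude weighting: a Gaussian KDE of log amplitudes (bandwidth 0.25 of
the spread — the rule-of-thumb bandwidth oversmooths clusters that sit
decades apart); group boundaries at valleys of the density, located as
local minima of the density or convex local minima of its second
derivative.  Group g's raw weight is n_carbons / (number of peaks at or
above g's lower boundary); weights are normalised so the most intense
group carries exactly 1.  Fewer than three peaks form a single group.

## Assignment

`M[i][j] = g(δᵢ_scaled − δⱼ_exp)` under the per-nucleus error model; for
¹³C each entry is multiplied by the peak's amplitude weight `A_j` and,
for the t-th reuse of a peak, by the penalty `(1/(1+t))^k` (k = the
peak's amplitude-group rank; 1 = most intense).  Columns are replicated
`ceil(n_shifts/n_peaks)+1` times when shifts outnumber peaks.  The
matching minimises Σ −log M (floored at 1e−300) by the Hungarian
algorithm.  Stages: external linear scaling `(δ − b)/a` with known
factors; internal scaling by ordinary least squares of calculated on
assigned experimental shifts (one robustness pass dropping >3 MAD
residuals; slopes outside [0.8, 1.2] or fewer than three pairs fall
back to identity); reassignment; and for ¹³C a bias pass: for shift i,
bias = (Σ amplitude weights of unassigned peaks within ±10 ppm of its
peak) / (weight of its peak); shifts with bias > 1 are reassigned in
descending order, each to the largest-amplitude unassigned peak in its
window.  ¹H uses neither weights, penalties nor bias — integral proton
counts bound how often each multiplet may be used — and assigns each
methyl trio (mean of its three shifts) as a unit to a multiplet with at
least three protons of spare capacity before the remaining protons.
Equal-cost ties are made deterministic by sorting atoms by label and
peaks by position before matching.

## DP4

Per candidate, log-likelihood = Σ over nuclei and atoms of
log g(error); probabilities are the softmax across candidates (flat
prior), computed in log space, so 200 atoms at 10σ errors do not
underflow.  Default error models are single Gaussians of sd 2.3 ppm
(¹³C) and 0.19 ppm (¹H), conventional values for
mPW1PW91/6-311G(d)-class GIAO predictions; a fitted Gaussian mixture
(scikit-learn EM, fixed seed, five restarts, component sd floored at
1e−3 ppm) drops into the same container, with leave-one-group-out
refits available for cross-validation.  Boltzmann averaging over
conformers uses weights ∝ exp(−ΔE/RT) (energies in kJ/mol, default
298.15 K).

## Synthetic test bed

The generator emulates: first-order multiplets (binomial line ratios)
as damped complex sinusoids, frequency-domain injection of zero/first-
order phase error, polynomial baseline drift, a solvent multiplet and
complex Gaussian noise; and calculated-shift tables as a linear
distortion of the truth plus error-model draws, with decoys perturbed
per atom.  Defaults: 400 MHz / 4800 Hz sweep for ¹H (8192 points;
recovery studies use 4096 for speed at 0.59 Hz per processed point) and
100.6 MHz / 24 kHz sweep, 16384 points for ¹³C; linewidths 1.0–1.6 Hz;
line SNR ≥ 8 in recovery studies per the weakest multiplet line.  It
does **not** emulate strong coupling (roofing, second-order patterns),
¹³C satellites, radiation damping, solvent pre-saturation artefacts or
temperature drift; passing recovery tests therefore demonstrate correct
behaviour for near-first-order spectra with smooth baselines, not for
strongly-coupled or artefact-heavy data.  Study sizes (100 spectra for
phase/multiplet recovery, 50 BIC trials, 100 end-to-end replicates,
10000 error-model draws) are the package's documented standard; the
acceptance script exposes a `--scale` knob for quick reduced runs.

## Known limitations

* Multiplicity (J-coupling) analysis, 2D spectra and compound mixtures
  are out of scope; degenerate ¹³C peaks are handled by multiple
  assignment, never by splitting a fitted peak.
* The 1% integral-convergence criterion is treated as a target, not an
  invariant: at finite SNR the region integral itself fluctuates by
  more than 1% and the fit stops at the noise floor.
* Phase recovery to 5° in both parameters needs signals near the sweep
  edges (see identifiability above); spectra with a narrow chemical-
  shift range are phased accurately *at their signals* but the reported
  (φ0, φ1) split along the trade-off valley is then arbitrary.
* The solvent table covers the four solvents the pipeline expects
  (chloroform, methanol, benzene, DMSO) and is user-extensible.
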