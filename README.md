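# autonmr

Automated processing of raw 1D NMR data and Bayesian ranking of
candidate structures.

Determining relative stereochemistry (or resolving other structural
ambiguity) by NMR typically means computing GIAO-DFT chemical shifts for
every candidate diastereomer and comparing them with the experimental
spectrum.  The comparison step — turning raw spectrometer output into
peak lists and integrals, and deciding which calculated shift belongs to
which experimental peak — is the slow, manual, error-prone part.
`autonmr` automates it end to end:

1. **Processing.**  Read a Bruker-style acquisition directory or JCAMP-DX
   file, apodize, Fourier transform, estimate noise, correct zero- and
   first-order phase (per-region phase estimates, weighted linear
   regression across the sweep, entropy-guarded refinement), and remove
   the baseline.
2. **Peak analysis.**  For ¹H: derivative peak picking with adaptive
   noise thresholds, grouping of peaks closer than 18 Hz into
   multiplets, deconvolution of each region into generalized Lorentzians
   (Lorentzian–Gaussian mixtures) iterated to a 1% integral criterion,
   deletion of noise components by Bayesian-Information-Criterion model
   selection, solvent-peak identification/removal with re-referencing,
   and normalisation of integrals to integer proton counts.  For ¹³C:
   greedy iterative Lorentzian picking down to the 3σ noise stopping
   rule, and amplitude weighting of peaks via a kernel-density grouping
   of peak amplitudes.
3. **Assignment.**  A probability matrix *M*, where
   *M*ᵢⱼ = P(calculated shift *i* ↔ experimental peak *j*) under a
   Gaussian(-mixture) model of shift-prediction errors, is solved by
   Hungarian minimisation of −log *M*.  Systematic prediction error is
   removed in stages: external scaling factors, then internal scaling
   regressed from the first assignment, then (¹³C) a bias pass that
   rescues intense unassigned peaks.  ¹³C peaks may be assigned more
   than once under the penalty (1/(1+t))ᵏ; ¹H assignment is bounded by
   the integral proton counts, with methyl trios assigned as units.
4. **DP4.**  Per candidate *c*, the likelihood is
   ∏ₐ g(δᵃ_calc − δᵃ_exp) over assigned atoms (and over nuclei,
   independently), with g the error density; the DP4 probability is the
   flat-prior posterior P(c) = Lc / Σ L, computed in log space.

## Worked example

```python
import numpy as np
from autonmr.synthetic import fixture_library, simulate_fid
from autonmr.spectra_io import transform
from autonmr import preprocessing as pre
from autonmr.proton import process_proton

spec = fixture_library()["h1_clean"]        # 4 multiplets, 7 protons
fid, truth = simulate_fid(spec)
s = transform(fid)
sigma = pre.estimate_noise(s)
regions = pre.classify_signal_regions(s, sigma)
s, phase = pre.phase_correct(s, regions)
s = pre.baseline_correct(s, regions)
pre.estimate_noise(s)
result = process_proton(s, total_protons=7, labile_protons=0)
for m in result["multiplets"]:
    print(f"{m.center:7.3f} ppm  integral {m.raw_integral:6.2f}  {m.proton_count}H")
```

prints

```
  1.050 ppm  integral  18.02  3H
  2.451 ppm  integral  12.08  2H
  4.100 ppm  integral   5.86  1H
  7.350 ppm  integral   5.97  1H
```

i.e. the four generating multiplets (1.05/2.45/4.10/7.35 ppm) recovered
with integrals in the 3:2:1:1 ratio and integer proton counts fixed by
the normalisation search.  Feeding per-candidate calculated shifts to
`autonmr.assignment.assign_protons` / `assign_carbons` and the resulting
errors to `autonmr.dp4.dp4` yields the DP4 table; the `autonmr` command
line (`autonmr all config.yaml`) runs the whole chain from raw data and
writes per-stage reports.

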