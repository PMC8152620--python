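import logging
import warnings

import numpy as np
import pytest

from autonmr import preprocessing as pre
from autonmr.spectra_io import transform
from autonmr.synthetic import MultipletSpec, SpectrumSpec, simulate_fid

logging.getLogger("autonmr").setLevel(logging.ERROR)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def clean_proton_spec() -> SpectrumSpec:
    """Four well-separated multiplets, 7 protons, mild noise."""
    return SpectrumSpec(
        multiplets=[
            MultipletSpec(1.05, "doublet", 6.8, width=1.0, protons=3),
            MultipletSpec(2.45, "triplet", 7.2, width=1.2, protons=2),
            MultipletSpec(4.10, "quartet", 7.0, width=1.2, protons=1),
            MultipletSpec(7.35, "singlet", width=1.0, protons=1),
        ],
        noise_sd=0.8,
        points=4096,
        seed=11,
    )


def prepare(spec: SpectrumSpec):
    """Simulate -> transform -> noise -> phase -> baseline."""
    fid, truth = simulate_fid(spec)
    s = transform(fid)
    sigma = pre.estimate_noise(s)
    regions = (
        pre.classify_signal_regions(s, sigma)
        if sigma > 0
        else pre.SignalRegions([], s.n_points)
    )
    s2, phase = pre.phase_correct(s, regions)
    s3 = pre.baseline_correct(s2, regions)
    pre.estimate_noise(s3)
    return s3, phase, truth


@pytest.fixture
def processed_clean_proton(clean_proton_spec):
    return prepare(clean_proton_spec)
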