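"""Shared fixtures: small-scale acquisition scenarios that run in seconds.

The desk-scale transducer (2-8 MHz band at 20 MS/s) keeps records short
while preserving every structural property of the reference operating
point (50 MHz / 112% band at 200 MS/s), which the acceptance tests use.
"""

import math

import numpy as np
import pytest
from hypothesis import settings

import fwmot as fw

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_band() -> fw.TransducerBand:
    return fw.TransducerBand.from_center(5e6, 1.2)   # 2-8 MHz


@pytest.fixture(scope="session")
def small_transducer(small_band) -> fw.TransducerModel:
    return fw.TransducerModel(band=small_band, focal_length=5e-3,
                              acceptance_half_angle=math.radians(30.0))


@pytest.fixture(scope="session")
def small_fs() -> float:
    return 20e6


@pytest.fixture(scope="session")
def reference_band() -> fw.TransducerBand:
    return fw.TransducerBand(22e6, 78e6)


@pytest.fixture
def single_train_scheme() -> fw.MultiplexScheme:
    """One wavelength, 100 kHz, 20 pulses, 100 nJ per pulse."""
    return fw.MultiplexScheme.fwm(100e3, 0.0, 20, pulse_energies=100e-9,
                                  n_wavelengths=1)


@pytest.fixture
def single_absorber() -> list:
    # 3 mm depth -> 2 us arrival; 1e5 V/J puts the wavelet peak at 10 mV
    return [fw.Absorber(depth=3e-3, per_wavelength_amplitude=(1e5,))]


@pytest.fixture
def quiet_noise() -> fw.NoiseModel:
    return fw.NoiseModel(seed=7)


def peak_in_window(ascan: fw.AveragedAScan, window) -> float:
    sl = slice(int(round(window[0] * ascan.sampling_rate)),
               int(round(window[1] * ascan.sampling_rate)))
    return float(np.max(np.abs(ascan.samples[sl])))
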