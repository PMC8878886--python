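"""Shared fixtures: small acquisition grids and synthetic line spectra."""

from __future__ import annotations

import math

import numpy as np
import pytest

from plasmanmr.simulate import FID, AcquisitionParams
from plasmanmr.preprocess import (apodize, fourier_transform,
                                  scale_first_point, zero_fill)


@pytest.fixture()
def acq_small() -> AcquisitionParams:
    """Short acquisition (4096 points) for fast spectral tests."""
    return AcquisitionParams(n_points_td=4096)


def synth_fid(lines, acq: AcquisitionParams, noise_sd: float = 0.0,
              phi0_deg: float = 0.0, phi1_deg: float = 0.0,
              shift_ppm: float = 0.0, seed: int = 0) -> FID:
    """FID as a sum of decaying complex sinusoids.

    ``lines`` is a list of (center_ppm, amplitude, fwhm_hz).  Optional global
    phase errors (phi1 over the normalized frequency coordinate), a chemical
    shift offset, and complex Gaussian noise.
    """
    n = acq.n_points_td
    dwell = acq.dwell_s
    t = np.arange(n) * dwell
    signal = np.zeros(n, dtype=complex)
    for ppm, amp, fwhm in lines:
        f = (ppm + shift_ppm - acq.carrier_ppm) * acq.spectrometer_freq_mhz
        phase = math.radians(phi0_deg) + math.radians(phi1_deg) * (f * dwell)
        signal += amp * np.exp(1j * (2 * math.pi * f * t + phase)
                               - math.pi * fwhm * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, noise_sd, size=(n, 2))
        signal = signal + noise[:, 0] + 1j * noise[:, 1]
    return FID(points=signal, dwell_s=dwell, acquisition=acq)


def synth_spectrum(lines, acq: AcquisitionParams, lb_hz: float = 1.0,
                   noise_sd: float = 0.0, seed: int = 0,
                   calibrated: bool = True):
    """Absorption spectrum of ``lines`` after apodize -> zero-fill -> FT.

    The synthesized FID is phase-perfect, so the real part is already
    absorption mode; the reported linewidth of each line is fwhm + lb.
    """
    fid = synth_fid(lines, acq, noise_sd=noise_sd, seed=seed)
    spec = fourier_transform(zero_fill(scale_first_point(apodize(fid, lb_hz)), 2))
    spec.calibrated = calibrated
    return spec
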