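"""Gaussian low-pass filtering shared by the simulator and the analysis chain.

The cutoff convention is the -3 dB point of a Gaussian kernel, the standard
in single-channel electrophysiology: a kernel with temporal standard
deviation sigma_t = 0.1325/fc attenuates a sinusoid at fc by exactly 1/sqrt(2).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

#: sigma_t * fc for a -3 dB cutoff at fc (exp(-2 pi^2 sigma_t^2 fc^2) = 2^-1/2)
SIGMA_FC = 0.1325

#: 10-90% rise time * fc of the same kernel
RISETIME_FC = 0.3321


def gaussian_lowpass(x: np.ndarray, fc: float, sampling_rate: float) -> np.ndarray:
    """Low-pass filter samples with a Gaussian kernel (-3 dB at ``fc``).

    Edges are handled by reflection; the output has the same length as the
    input. Raises ``ValueError`` if ``fc`` is at or above Nyquist.
    """
    if fc <= 0:
        raise ValueError("cutoff frequency must be positive")
    if fc >= sampling_rate / 2:
        raise ValueError(
            f"cutoff {fc} Hz is at or above Nyquist ({sampling_rate / 2} Hz)"
        )
    sigma_samples = SIGMA_FC / fc * sampling_rate
    return gaussian_filter1d(np.asarray(x, dtype=float), sigma_samples, mode="reflect")


def noise_bandwidth_factor(fc: float, sampling_rate: float) -> float:
    """Theoretical ratio of output to input white-noise standard deviation.

    For a normalized Gaussian kernel, sum(h^2) = 1/(2 sqrt(pi) sigma_samples);
    the output sigma is the input sigma times sqrt of that.
    """
    sigma_samples = SIGMA_FC / fc * sampling_rate
    return float(1.0 / np.sqrt(2.0 * np.sqrt(np.pi) * sigma_samples))
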