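"""Hemodynamic response model for the CBV simulator.

The impulse response is a unimodal, causal gamma-density kernel
re-parameterized by its peak delay and full width at half maximum and
normalized to unit peak, so a trial of matched preference produces a
ΔCBV excursion whose maximum equals ``response_amplitude`` percent at
``peak_delay`` seconds after stimulus onset (2.5 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist

__all__ = ["HemodynamicModel", "gamma_kernel_params"]


def _gamma_fwhm(shape: float, peak: float) -> float:
    """FWHM of a gamma pdf with given shape, rescaled so its mode is ``peak``."""
    if shape <= 1.0:
        return 1e6
    scale = peak / (shape - 1.0)
    dist = gamma_dist(shape, scale=scale)
    half = dist.pdf(peak) / 2.0

    def f(t):
        return dist.pdf(t) - half

    if f(1e-9) >= 0:  # too flat: half-max never crossed below the mode
        return 1e6
    lo = brentq(f, 1e-9, peak)
    # upper half-max crossing is beyond the mode; bracket generously
    hi = brentq(f, peak, peak + 50.0 * scale * np.sqrt(shape))
    return hi - lo


def gamma_kernel_params(peak_delay: float, fwhm: float) -> tuple[float, float]:
    """Solve for the gamma (shape, scale) with a given mode and FWHM."""
    if peak_delay <= 0 or fwhm <= 0:
        raise ValueError("peak_delay and fwhm must be positive")

    def f(shape):
        return _gamma_fwhm(shape, peak_delay) - fwhm

    shape = brentq(f, 1.0 + 1e-6, 5000.0)
    return shape, peak_delay / (shape - 1.0)


@dataclass
class HemodynamicModel:
    """Trial-evoked CBV response: tuned amplitude x unit-peak gamma kernel.

    Parameters
    ----------
    peak_delay
        Seconds from stimulus onset to the CBV peak (default 2.5 s).
    fwhm
        Kernel full width at half maximum in seconds (default 2 s).
    response_amplitude
        Peak ΔCBV in percent of baseline for a perfectly matched
        condition (default 16%, the scale of a short-flash response).
    tuning_width_ecc, tuning_width_ang
        Gaussian tuning SD in DVA / degrees used by the simulator to
        scale responses by |condition - pixel preference|.
    """

    peak_delay: float = 2.5
    fwhm: float = 2.0
    response_amplitude: float = 16.0
    tuning_width_ecc: float = 1.5
    tuning_width_ang: float = 15.0
    _shape_scale: tuple[float, float] = field(init=False, repr=False)

    def __post_init__(self):
        self._shape_scale = gamma_kernel_params(self.peak_delay, self.fwhm)

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Unit-peak causal kernel evaluated at times ``t`` (s post-onset)."""
        t = np.asarray(t, dtype=float)
        shape, scale = self._shape_scale
        k = gamma_dist.pdf(t, shape, scale=scale)
        peak = gamma_dist.pdf(self.peak_delay, shape, scale=scale)
        out = np.where(t >= 0, k / peak, 0.0)
        return out

    def tuning_weight(
        self, condition_value: float, preference: np.ndarray, kind: str
    ) -> np.ndarray:
        """Gaussian tuning factor in [0, 1] for a retinotopic condition."""
        width = (
            self.tuning_width_ecc if kind == "eccentricity" else self.tuning_width_ang
        )
        return np.exp(-0.5 * ((condition_value - preference) / width) ** 2)
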