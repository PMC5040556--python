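"""Gamma hemodynamic response function and event-to-regressor convolution.

A single-gamma HRF with a 6 s peak delay and 3 s dispersion is used both to
synthesize BOLD responses and to build the lag-shifted reference models and
GLM design matrices, so the hemodynamic delay is accounted for identically on
the generation and analysis sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HRFParams", "gamma_hrf", "oversampled_regressor", "sample_to_tr"]


@dataclass(frozen=True)
class HRFParams:
    """Single-gamma HRF parameters.

    peak_delay and dispersion are the mode and width (seconds) of the gamma
    density; undershoot_ratio scales a delayed negative gamma lobe (0 disables
    it); duration is the kernel support in seconds.
    """

    peak_delay: float = 6.0
    dispersion: float = 3.0
    undershoot_ratio: float = 0.0
    duration: float = 24.0

    def __post_init__(self) -> None:
        if self.peak_delay <= 0:
            raise ValueError("peak_delay must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.undershoot_ratio < 0 or self.undershoot_ratio >= 1:
            raise ValueError("undershoot_ratio must be in [0, 1)")
        if self.duration <= self.peak_delay:
            raise ValueError("duration must exceed peak_delay")


def _gamma_density(t: np.ndarray, mode: float, dispersion: float) -> np.ndarray:
    # Parameterize by the mode: for shape k>1, mode = (k-1)*theta.
    theta = dispersion**2 / mode
    k = mode / theta + 1.0
    return stats.gamma.pdf(t, a=k, scale=theta)


def gamma_hrf(tr: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sample the gamma HRF kernel at interval ``tr``, normalized to unit peak.

    The kernel has ``round(duration / tr)`` samples and its argmax lies within
    one sample of ``params.peak_delay``.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    n = int(round(params.duration / tr))
    if n < 1:
        raise ValueError("duration must cover at least one sample")
    t = np.arange(n) * tr
    h = _gamma_density(t, params.peak_delay, params.dispersion)
    if params.undershoot_ratio > 0:
        under = _gamma_density(t, params.peak_delay * 2.0, params.dispersion * 1.5)
        if under.max() > 0:
            h = h - params.undershoot_ratio * under / under.max() * h.max()
    peak = np.abs(h).max()
    if peak <= 0:
        raise ValueError("degenerate HRF kernel")
    return h / h.max()


def oversampled_regressor(
    indicator: np.ndarray, dt: float, hrf_params: HRFParams
) -> np.ndarray:
    """Convolve a fine-grid activation indicator with the unit-peak HRF.

    Returns the linear convolution truncated to the indicator's length.
    """
    kernel = gamma_hrf(dt, hrf_params)
    return np.convolve(indicator, kernel)[: len(indicator)]


def sample_to_tr(fine: np.ndarray, oversample: int, n_volumes: int) -> np.ndarray:
    """Pick one sample per TR (at each volume's acquisition onset)."""
    idx = np.arange(n_volumes) * oversample
    if idx[-1] >= len(fine):
        raise ValueError("fine-grid signal shorter than requested volumes")
    return fine[idx]
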