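"""Synthetic 4D BOLD phantoms with known digit topography.

The generator emulates what the mapping analysis consumes: a strip of voxels
with a spatially ordered digit preference (mimicking the S1 digit gradient),
gamma-HRF responses to travelling-wave or block schedules, Gaussian tuning
falloff to neighbouring digits, AR(1) noise plus slow sinusoidal drift, and —
for the similarity analysis — block-design multivoxel patterns drawn from a
specified inter-digit second-moment matrix plus a common (shared) pattern.
Because the ground truth is known, every downstream stage (winner-take-all
mapping, Dice consistency, pattern-component correlations) can be verified
against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.optimize import brentq

from .hrf import HRFParams, gamma_hrf, oversampled_regressor, sample_to_tr
from .paradigm import BlockSchedule, MovementSchedule, schedule_duration
from .volume import Volume4D, save_int_volume

__all__ = [
    "HRFParams",
    "gamma_hrf",
    "Volume4D",
    "GroundTruthMap",
    "NoiseModel",
    "PatternGroundTruth",
    "make_digit_strip",
    "simulate_run",
    "digit_regressors",
    "simulate_block_patterns",
    "pair_correlated_second_moment",
    "write_ground_truth",
]


@dataclass
class GroundTruthMap:
    """Per-voxel digit preference used to synthesize and score recovery.

    preferred_digit: 0 marks a non-responsive voxel, 1..5 a digit band.
    amplitude: response amplitude in % signal change units.
    tuning_width: Gaussian falloff (in digit units) of the response to
    neighbouring digits; 0 means the voxel responds to its digit only.
    """

    preferred_digit: np.ndarray
    amplitude: np.ndarray
    tuning_width: np.ndarray

    def __post_init__(self) -> None:
        self.preferred_digit = np.asarray(self.preferred_digit, dtype=int)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.tuning_width = np.asarray(self.tuning_width, dtype=float)
        if not (
            self.preferred_digit.shape
            == self.amplitude.shape
            == self.tuning_width.shape
        ):
            raise ValueError("ground-truth fields must share one grid shape")
        if self.preferred_digit.min() < 0 or self.preferred_digit.max() > 5:
            raise ValueError("preferred_digit must lie in 0..5")
        if (self.amplitude < 0).any():
            raise ValueError("amplitude must be >= 0")
        if (self.tuning_width < 0).any():
            raise ValueError("tuning_width must be >= 0")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.preferred_digit.shape

    @property
    def responsive(self) -> np.ndarray:
        return self.preferred_digit > 0


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: stationary AR(1) Gaussian plus sinusoidal drift."""

    sigma: float = 1.0
    drift_amplitude: float = 0.5
    drift_period: float = 128.0
    ar_coefficient: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be > 0")


@dataclass
class PatternGroundTruth:
    """Generative model for block-design digit patterns.

    One true pattern per digit with the given 5x5 second moment across digits,
    one shared common pattern scaled by common_amplitude, and independent
    Gaussian measurement noise per run.
    """

    second_moment: np.ndarray
    n_voxels: int = 2000
    n_runs: int = 4
    noise_sigma: float = 0.5
    common_amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.second_moment = np.asarray(self.second_moment, dtype=float)
        if self.second_moment.shape != (5, 5):
            raise ValueError("second_moment must be 5x5")
        if not np.allclose(self.second_moment, self.second_moment.T):
            raise ValueError("second_moment must be symmetric")
        if np.linalg.eigvalsh(self.second_moment).min() < -1e-10:
            raise ValueError("second_moment must be positive semi-definite")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if self.n_voxels < 5:
            raise ValueError("n_voxels must be >= 5")
        if self.noise_sigma < 0 or self.common_amplitude < 0:
            raise ValueError("noise_sigma and common_amplitude must be >= 0")


def make_digit_strip(
    grid_shape: tuple[int, int, int],
    n_digits: int = 5,
    strip_axis: int = 0,
    band_width_voxels: int = 3,
    amplitude: float = 1.0,
    tuning_width: float = 0.5,
) -> GroundTruthMap:
    """Contiguous ordered digit bands along one axis (a digit-gradient strip).

    Voxels outside the ``n_digits * band_width_voxels`` extent along the strip
    axis are non-responsive, so band d touches only bands d-1 and d+1.
    """
    if band_width_voxels < 1:
        raise ValueError("band_width_voxels must be >= 1")
    extent = grid_shape[strip_axis]
    if n_digits * band_width_voxels > extent:
        raise ValueError(
            f"{n_digits} bands of {band_width_voxels} voxels do not fit "
            f"axis extent {extent}"
        )
    pref = np.zeros(grid_shape, dtype=int)
    coord = np.arange(extent)
    band = np.where(
        coord < n_digits * band_width_voxels, coord // band_width_voxels + 1, 0
    )
    shape = [1, 1, 1]
    shape[strip_axis] = extent
    pref += band.reshape(shape)
    amp = np.where(pref > 0, amplitude, 0.0)
    tw = np.where(pref > 0, tuning_width, 0.0)
    return GroundTruthMap(preferred_digit=pref, amplitude=amp, tuning_width=tw)


def digit_regressors(
    schedule: MovementSchedule | BlockSchedule,
    tr: float,
    hrf: HRFParams = HRFParams(),
    n_volumes: int | None = None,
    n_digits: int = 5,
    oversample: int = 10,
) -> np.ndarray:
    """HRF-convolved per-digit activation regressors, shape (n_digits, T).

    Built on an oversampled grid (dt = tr / oversample) from the schedule's
    movement events, then sampled at each volume onset.  The same routine
    underlies the simulator and the GLM design matrix.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    duration = schedule_duration(schedule)
    if n_volumes is None:
        n_volumes = int(np.floor(duration / tr + 1e-9))
    if n_volumes < 1:
        raise ValueError("schedule must cover at least one volume")
    dt = tr / oversample
    n_fine = n_volumes * oversample + oversample
    events = (
        schedule.digit_events()
        if isinstance(schedule, BlockSchedule)
        else list(schedule.events)
    )
    regs = np.zeros((n_digits, n_volumes))
    for d in range(1, n_digits + 1):
        ind = np.zeros(n_fine)
        for ev in events:
            if ev.digit != d:
                continue
            i0 = int(round(ev.onset / dt))
            i1 = int(round(ev.offset / dt))
            ind[i0 : min(i1, n_fine)] = 1.0
        fine = oversampled_regressor(ind, dt, hrf)
        regs[d - 1] = sample_to_tr(fine, oversample, n_volumes)
    return regs


def _tuning_weights(truth: GroundTruthMap, n_digits: int = 5) -> np.ndarray:
    """Per-voxel response weight to each digit, shape (n_voxels, n_digits)."""
    pref = truth.preferred_digit.ravel().astype(float)
    amp = truth.amplitude.ravel()
    tw = truth.tuning_width.ravel()
    digits = np.arange(1, n_digits + 1, dtype=float)
    dist = np.abs(digits[None, :] - pref[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(
            tw[:, None] > 0,
            np.exp(-(dist**2) / (2.0 * np.maximum(tw[:, None], 1e-300) ** 2)),
            (dist == 0).astype(float),
        )
    w *= amp[:, None]
    w[pref == 0] = 0.0
    return w


def simulate_run(
    schedule: MovementSchedule | BlockSchedule,
    truth: GroundTruthMap,
    hrf: HRFParams = HRFParams(),
    tr: float = 1.5,
    noise: NoiseModel = NoiseModel(),
    n_volumes: int | None = None,
    oversample: int = 10,
) -> Volume4D:
    """Synthesize one 4D BOLD run for the given schedule and ground truth.

    Each responsive voxel's signal is the amplitude-weighted, Gaussian-tuned
    sum of HRF-convolved digit indicators; all voxels receive AR(1) noise and
    a sinusoidal drift with a per-voxel random phase.  Deterministic for a
    fixed seed.
    """
    duration = schedule_duration(schedule)
    if n_volumes is None:
        n_volumes = int(np.floor(duration / tr + 1e-9))
    if n_volumes * tr < tr:
        raise ValueError("schedule must span at least one TR")
    regs = digit_regressors(schedule, tr, hrf, n_volumes, oversample=oversample)
    weights = _tuning_weights(truth)  # (V, 5)
    sig = weights @ regs  # (V, T)

    rng = np.random.default_rng(noise.seed)
    n_vox = sig.shape[0]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_vox)
    white = rng.standard_normal((n_vox, n_volumes))
    if noise.sigma > 0 and noise.ar_coefficient > 0:
        innov_sd = noise.sigma * np.sqrt(1.0 - noise.ar_coefficient**2)
        colored = sp_signal.lfilter(
            [1.0], [1.0, -noise.ar_coefficient], innov_sd * white, axis=1
        )
    else:
        colored = noise.sigma * white
    t = np.arange(n_volumes) * tr
    drift = noise.drift_amplitude * np.sin(
        2.0 * np.pi * t[None, :] / noise.drift_period + phases[:, None]
    )
    data = (sig + colored + drift).reshape(truth.grid_shape + (n_volumes,))
    return Volume4D(data=data, tr=tr)


def simulate_block_patterns(truth: PatternGroundTruth, seed: int = 0) -> np.ndarray:
    """Draw run-wise digit patterns, shape (n_runs, 5, n_voxels).

    One true pattern per digit (second moment across digits =
    ``truth.second_moment``), plus one shared common pattern scaled by
    ``common_amplitude``, plus independent per-run Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    w, v = np.linalg.eigh(truth.second_moment)
    w = np.clip(w, 0.0, None)
    factor = v @ np.diag(np.sqrt(w))  # G = factor @ factor.T
    x = rng.standard_normal((5, truth.n_voxels))
    digit_patterns = factor @ x
    common = truth.common_amplitude * rng.standard_normal(truth.n_voxels)
    runs = np.empty((truth.n_runs, 5, truth.n_voxels))
    for r in range(truth.n_runs):
        noise = truth.noise_sigma * rng.standard_normal((5, truth.n_voxels))
        runs[r] = digit_patterns + common[None, :] + noise
    return runs


def pair_correlated_second_moment(
    r: float, pair: tuple[int, int] = (0, 1), n_digits: int = 5
) -> np.ndarray:
    """Generative second moment whose common-removed pair correlation is ``r``.

    The pattern-component analysis identifies digit components only net of
    the across-digit mean (centering matrix C = I - J/n), so a requested
    "true correlation r between digits i and j" must hold for the centered
    second moment C G C.  This solves for G = I + a(EiEj' + EjEi') such that
    corr(C G C)[i, j] = r exactly.
    """
    i, j = pair
    if i == j:
        raise ValueError("pair must name two distinct digits")
    c = np.eye(n_digits) - np.ones((n_digits, n_digits)) / n_digits

    def centered_corr(alpha: float) -> float:
        g = np.eye(n_digits)
        g[i, j] = g[j, i] = alpha
        b = c @ g @ c
        return b[i, j] / np.sqrt(b[i, i] * b[j, j])

    lo, hi = -0.999, 0.999
    if not (centered_corr(lo) <= r <= centered_corr(hi)):
        raise ValueError(
            f"target correlation {r} not achievable; range is "
            f"[{centered_corr(lo):.3f}, {centered_corr(hi):.3f}]"
        )
    alpha = brentq(lambda a: centered_corr(a) - r, lo, hi, xtol=1e-12)
    g = np.eye(n_digits)
    g[i, j] = g[j, i] = alpha
    return g


def write_ground_truth(truth: GroundTruthMap, path_prefix) -> None:
    """Write the preferred-digit volume (NIfTI) plus a JSON parameter sidecar."""
    save_int_volume(truth.preferred_digit, f"{path_prefix}.nii.gz")
    meta = {
        "grid_shape": list(truth.grid_shape),
        "amplitude_max": float(truth.amplitude.max(initial=0.0)),
        "tuning_width_max": float(truth.tuning_width.max(initial=0.0)),
        "n_responsive": int(truth.responsive.sum()),
    }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2)
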