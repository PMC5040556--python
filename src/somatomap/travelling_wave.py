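"""Winner-take-all lag cross-correlation mapping (phase-encoding analysis).

The engine builds one HRF-convolved periodic boxcar reference model per lag
of the movement cycle (L = cycle_duration / tr lags; 30 for the 45 s cycle at
TR 1.5 s, 35 for the 45.5 s cycle at TR 1.3 s), Pearson-correlates every
voxel's time course against every model, Fisher-transforms the r values,
time-reverses backward-run profiles onto the forward lag axis, averages the
lags belonging to each digit (L / n_digits contiguous lags per digit, six for
the canonical protocol), and assigns each voxel to its winning digit.  Digit
masks are thresholded either at a fixed Z or by Benjamini-Hochberg FDR within
each digit's candidate voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .hrf import HRFParams, gamma_hrf
from .volume import Volume4D

__all__ = [
    "ReferenceModelBank",
    "LagProfile",
    "DigitPreferenceMap",
    "GradientMap",
    "build_reference_models",
    "fisher_z",
    "lag_crosscorrelate",
    "reverse_lag_profile",
    "average_profiles",
    "assign_digits",
    "winner_take_all",
    "fdr_threshold",
    "gradient_map",
    "analyse_runs",
    "map_digits",
]


@dataclass
class ReferenceModelBank:
    """L lag-shifted reference models, each sampled at every volume onset.

    models has shape (L, n_volumes); model ``lag`` is the HRF-convolved
    periodic boxcar whose "on" period starts ``lag * tr`` seconds into each
    cycle (circular within the cycle), preceded by ``lead_in`` seconds of rest.
    """

    models: np.ndarray
    tr: float
    cycle_duration: float
    n_cycles: int
    on_duration: float
    lead_in: float = 0.0

    @property
    def n_lags(self) -> int:
        return self.models.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.models.shape[1]

    @property
    def on_lags(self) -> int:
        return int(round(self.on_duration / self.tr))


@dataclass
class LagProfile:
    """Per-voxel standardized correlation (Fisher z) at each cycle lag.

    z has shape grid_shape + (L,).  ``on_lags`` records how many lags one
    digit block spans; time reversal needs it to keep digit phase aligned.
    """

    z: np.ndarray
    tr: float
    on_lags: int
    n_volumes: int

    @property
    def n_lags(self) -> int:
        return self.z.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.z.shape[:-1]


@dataclass
class DigitPreferenceMap:
    """Winner-take-all digit assignment.

    winner: per-voxel digit 1..n (0 = unassigned); winner_z: the winning
    averaged Fisher z; digit_masks: (n_digits,) + grid booleans, pairwise
    disjoint, each voxel's mask matching its winner.
    """

    winner: np.ndarray
    winner_z: np.ndarray
    digit_masks: np.ndarray
    n_volumes: int

    @property
    def n_digits(self) -> int:
        return self.digit_masks.shape[0]


@dataclass
class GradientMap:
    """Per-voxel winning lag (0..L-1), visualizing the digit-phase gradient."""

    winning_lag: np.ndarray
    n_lags: int


def build_reference_models(
    tr: float,
    cycle_duration: float,
    n_cycles: int,
    on_duration: float,
    hrf: HRFParams = HRFParams(),
    lead_in: float = 0.0,
    n_volumes: int | None = None,
    oversample: int = 10,
) -> ReferenceModelBank:
    """Construct the L = cycle_duration / tr lag-shifted reference models.

    The lag-0 boxcar is "on" for ``on_duration`` at the start of every cycle;
    lag ``l`` circularly shifts the boxcar by ``l * tr`` within the cycle
    before HRF convolution.  ``cycle_duration`` must be commensurate with
    ``tr``.
    """
    if tr <= 0 or cycle_duration <= 0 or on_duration <= 0:
        raise ValueError("tr, cycle_duration and on_duration must be > 0")
    n_lags = int(round(cycle_duration / tr))
    if abs(n_lags * tr - cycle_duration) > 1e-6 * cycle_duration:
        raise ValueError(
            f"cycle_duration {cycle_duration} is not an integer multiple of tr {tr}"
        )
    dt = tr / oversample
    cycle_samples = n_lags * oversample
    total = lead_in + n_cycles * cycle_duration
    if n_volumes is None:
        n_volumes = int(np.floor(total / tr + 1e-9))
    lead_samples = int(round(lead_in / dt))
    n_on = int(round(on_duration / dt))

    base_cycle = np.zeros(cycle_samples)
    base_cycle[:n_on] = 1.0
    kernel = gamma_hrf(dt, hrf)
    n_fine = lead_samples + n_cycles * cycle_samples
    need = n_volumes * oversample + 1
    models = np.empty((n_lags, n_volumes))
    for lag in range(n_lags):
        shifted = np.roll(base_cycle, lag * oversample)
        fine = np.zeros(max(n_fine, need))
        fine[lead_samples : lead_samples + n_cycles * cycle_samples] = np.tile(
            shifted, n_cycles
        )
        conv = np.convolve(fine, kernel)[: len(fine)]
        models[lag] = conv[np.arange(n_volumes) * oversample]
    return ReferenceModelBank(
        models=models,
        tr=tr,
        cycle_duration=cycle_duration,
        n_cycles=n_cycles,
        on_duration=on_duration,
        lead_in=lead_in,
    )


def fisher_z(r):
    """Fisher's variance-stabilizing r-to-z transform, atanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def lag_crosscorrelate(vol: Volume4D, bank: ReferenceModelBank) -> LagProfile:
    """Pearson-correlate every voxel against every lag model, Fisher-transformed.

    Constant (zero-variance) time courses are defined to have z = 0 at all
    lags, marking them unassignable rather than undefined.
    """
    if vol.n_volumes != bank.n_volumes:
        raise ValueError(
            f"volume has {vol.n_volumes} volumes but models have {bank.n_volumes}"
        )
    if abs(vol.tr - bank.tr) > 1e-9:
        raise ValueError("volume and model bank must share one TR")
    x = vol.timecourses()
    x = x - x.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    ok = xn[:, 0] > 0
    x = np.divide(x, xn, out=np.zeros_like(x), where=xn > 0)
    m = bank.models - bank.models.mean(axis=1, keepdims=True)
    mn = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(mn == 0):
        raise ValueError("degenerate (constant) reference model")
    m = m / mn
    r = x @ m.T  # (V, L)
    r[~ok] = 0.0
    np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12, out=r)
    z = np.arctanh(r).reshape(vol.grid_shape + (bank.n_lags,))
    return LagProfile(z=z, tr=vol.tr, on_lags=bank.on_lags, n_volumes=vol.n_volumes)


def reverse_lag_profile(profile: LagProfile) -> LagProfile:
    """Map a backward-run lag profile onto the forward lag axis.

    Time reversal of the movement cycle sends a block starting at cycle
    offset s to one starting at (cycle - s - on_duration), so the digit-
    aligned reversal is z'[l] = z[(L - on_lags - l) mod L].  Applying the
    transform twice returns the input, and on noiseless data the reversed
    backward profile peaks at the same lag as the forward profile of the same
    voxel.
    """
    n_lags = profile.n_lags
    src = (n_lags - profile.on_lags - np.arange(n_lags)) % n_lags
    return replace(profile, z=profile.z[..., src])


def average_profiles(profiles: list[LagProfile]) -> LagProfile:
    """Element-wise mean of Fisher z across runs (lag-by-lag averaging)."""
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if p.z.shape != first.z.shape:
            raise ValueError("profiles must share one grid and lag count")
    z = np.mean([p.z for p in profiles], axis=0)
    return replace(first, z=z)


def assign_digits(
    profile: LagProfile, n_digits: int = 5, direction_reference: str = "forward"
) -> np.ndarray:
    """Average each digit's contiguous lag bin; returns grid + (n_digits,).

    Digit d's bin is the L / n_digits contiguous lags centred (circularly) on
    d's block-onset lag in the forward sequence — the lag where a voxel
    responding to digit d peaks, since the HRF delay lives inside the
    reference models.  Centring matters: a bin anchored at the onset and
    extending only forward would credit the entire left flank of a voxel's
    lag-tuning curve to the preceding digit, systematically misassigning
    edge digits whenever responses spill over to a neighbouring digit.
    ``direction_reference='backward'`` reverses the digit order of the bins.
    """
    n_lags = profile.n_lags
    if n_lags % n_digits != 0:
        raise ValueError(f"{n_lags} lags not divisible by {n_digits} digits")
    per = n_lags // n_digits
    rolled = np.roll(profile.z, per // 2, axis=-1)
    binned = rolled.reshape(profile.grid_shape + (n_digits, per)).mean(axis=-1)
    if direction_reference == "backward":
        binned = binned[..., ::-1]
    elif direction_reference != "forward":
        raise ValueError("direction_reference must be 'forward' or 'backward'")
    return binned


def winner_take_all(
    digit_values: np.ndarray, threshold_z: float | None = None, n_volumes: int = 0
) -> DigitPreferenceMap:
    """Assign each voxel to the digit with the highest averaged z.

    Ties break to the lowest digit index.  With ``threshold_z``, voxels whose
    winning z falls below it are left unassigned (winner 0, no mask).
    """
    digit_values = np.asarray(digit_values, dtype=float)
    n_digits = digit_values.shape[-1]
    winner = np.argmax(digit_values, axis=-1) + 1
    winner_z = np.take_along_axis(
        digit_values, (winner - 1)[..., None], axis=-1
    )[..., 0]
    if threshold_z is not None:
        assigned = winner_z >= threshold_z
        winner = np.where(assigned, winner, 0)
    masks = np.stack([(winner == d) for d in range(1, n_digits + 1)])
    return DigitPreferenceMap(
        winner=winner, winner_z=winner_z, digit_masks=masks, n_volumes=n_volumes
    )


def winner_p_values(winner_z: np.ndarray, n_volumes: int) -> np.ndarray:
    """One-sided normal p for Fisher z with standard error 1/sqrt(n-3)."""
    if n_volumes <= 3:
        raise ValueError("need more than 3 volumes for the Fisher z standard error")
    return stats.norm.sf(winner_z * np.sqrt(n_volumes - 3))


def bh_reject(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection set at level q."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def fdr_threshold(
    dpm: DigitPreferenceMap, q: float = 0.05, n_volumes: int | None = None
) -> DigitPreferenceMap:
    """Benjamini-Hochberg FDR thresholding within each digit's candidates.

    Per digit, one-sided p-values are derived from the winning-voxel z values
    and the step-up rule is applied at level q across that digit's candidate
    voxels only; survivors form the digit's mask.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    n_volumes = n_volumes if n_volumes is not None else dpm.n_volumes
    p = winner_p_values(dpm.winner_z, n_volumes)
    masks = np.zeros_like(dpm.digit_masks)
    for d in range(1, dpm.n_digits + 1):
        cand = dpm.winner == d
        if not cand.any():
            continue
        sel = np.zeros(dpm.winner.shape, dtype=bool)
        sel[cand] = bh_reject(p[cand], q)
        masks[d - 1] = sel
    winner = np.where(masks.any(axis=0), dpm.winner, 0)
    return DigitPreferenceMap(
        winner=winner,
        winner_z=dpm.winner_z,
        digit_masks=masks,
        n_volumes=n_volumes,
    )


def gradient_map(profile: LagProfile) -> GradientMap:
    """Winner-take-all across all lags (ties to the lowest lag)."""
    return GradientMap(
        winning_lag=np.argmax(profile.z, axis=-1), n_lags=profile.n_lags
    )


def analyse_runs(
    runs: list[tuple[Volume4D, str]], bank: ReferenceModelBank
) -> LagProfile:
    """Cross-correlate each run, time-reverse backward runs, and average.

    ``runs`` is a list of (volume, direction) with direction 'forward' or
    'backward'.
    """
    profiles = []
    for vol, direction in runs:
        prof = lag_crosscorrelate(vol, bank)
        if direction == "backward":
            prof = reverse_lag_profile(prof)
        elif direction != "forward":
            raise ValueError(f"unknown run direction {direction!r}")
        profiles.append(prof)
    return average_profiles(profiles)


def map_digits(
    runs: list[tuple[Volume4D, str]],
    bank: ReferenceModelBank,
    n_digits: int = 5,
    q: float | None = 0.05,
    threshold_z: float | None = None,
) -> tuple[DigitPreferenceMap, LagProfile]:
    """Full mapping: runs -> averaged profile -> winner map (FDR or Z cut)."""
    profile = analyse_runs(runs, bank)
    values = assign_digits(profile, n_digits)
    dpm = winner_take_all(values, threshold_z=threshold_z, n_volumes=profile.n_volumes)
    if q is not None:
        dpm = fdr_threshold(dpm, q=q, n_volumes=profile.n_volumes)
    return dpm, profile
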