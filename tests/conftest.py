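"""Shared fixtures: small phantoms and reference banks, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from somatomap import (
    HRFParams,
    NoiseModel,
    make_digit_strip,
    make_travelling_wave_schedule,
    simulate_run,
)
from somatomap.travelling_wave import build_reference_models

TR = 1.5
CYCLE = 45.0
N_CYCLES = 8
BLOCK = 9.0
LEAD_IN = 25.0


@pytest.fixture(scope="session")
def strip_truth():
    """15x5x5 strip phantom: five 3-voxel digit bands along x."""
    return make_digit_strip((15, 5, 5))


@pytest.fixture(scope="session")
def noiseless_truth():
    return make_digit_strip((15, 5, 5), tuning_width=0.0)


def noiseless_noise(seed: int = 0) -> NoiseModel:
    return NoiseModel(sigma=0.0, drift_amplitude=0.0, seed=seed)


@pytest.fixture(scope="session")
def noiseless_runs(noiseless_truth):
    """One forward + one backward run, no noise, no tuning spill."""
    runs = []
    for direction in ("forward", "backward"):
        sched = make_travelling_wave_schedule(
            direction, 5, BLOCK, N_CYCLES, LEAD_IN
        )
        runs.append(
            (simulate_run(sched, noiseless_truth, tr=TR, noise=noiseless_noise()),
             direction)
        )
    return runs


@pytest.fixture(scope="session")
def bank(noiseless_runs):
    n_volumes = noiseless_runs[0][0].n_volumes
    return build_reference_models(
        TR, CYCLE, N_CYCLES, BLOCK, HRFParams(), LEAD_IN, n_volumes=n_volumes
    )


def simulate_four_runs(truth, seed: int, sigma: float = 1.0, tr: float = TR):
    """Two forward + two backward runs at the given noise level."""
    runs = []
    for k, direction in enumerate(("forward", "backward", "forward", "backward")):
        sched = make_travelling_wave_schedule(direction, 5, BLOCK, N_CYCLES, LEAD_IN)
        noise = NoiseModel(sigma=sigma, seed=seed * 17 + k)
        runs.append((simulate_run(sched, truth, tr=tr, noise=noise), direction))
    return runs


def brute_force_bh(p_values: np.ndarray, q: float) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up, used as the independent oracle."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= q * (np.arange(1, m + 1) / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k_star = np.nonzero(below)[0].max()
        reject[order[: k_star + 1]] = True
    return reject
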