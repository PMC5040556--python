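"""Inter-digit representational similarity of block-design multivoxel patterns.

Digit activation patterns are estimated per run with an ordinary GLM (five
HRF-convolved digit regressors plus intercept, rest as implicit baseline).
The inter-digit "fingerprint" is then computed with a pattern-component
approach: each run's mean pattern across digits is removed (the common
component shared by all digits), and the digit-by-digit second moment is
estimated from cross-run inner products only, so measurement noise — which is
independent across runs — cancels in expectation.  The resulting correlations
are unbiased estimates of the true (common-removed) pattern correlations and
may legitimately fall outside [-1, 1]; they are reported raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .consistency import BootstrapResult
from .hrf import HRFParams
from .paradigm import BlockSchedule
from .synthetic import digit_regressors
from .volume import Volume4D

__all__ = [
    "DigitPatterns",
    "SimilarityMatrix",
    "ControlComparison",
    "glm_betas",
    "stack_runs",
    "pattern_component_similarity",
    "mean_overlap",
    "compare_to_controls",
    "off_diagonal_cells",
]


@dataclass
class DigitPatterns:
    """Run-wise digit activation estimates, betas shape (n_runs, 5, n_voxels)."""

    betas: np.ndarray
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (n_runs, n_digits, n_voxels)")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]


@dataclass
class SimilarityMatrix:
    """5x5 inter-digit pattern-correlation fingerprint.

    Diagonal is 1 by convention; ``undefined`` marks digits whose estimated
    pattern variance was non-positive (their correlations are NaN, reported
    rather than clamped).
    """

    r: np.ndarray
    g: np.ndarray | None = None
    undefined: np.ndarray = field(default_factory=lambda: np.zeros(5, dtype=bool))

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("similarity matrix must be square")

    @property
    def mean_overlap(self) -> float:
        return mean_overlap(self)


@dataclass(frozen=True)
class ControlComparison:
    """Single case versus a control population of similarity fingerprints.

    ``pair_rhos`` holds the Spearman correlation for every unordered control
    pair, ``case_rhos`` the case's correlation with each control; the CIs are
    bootstrap percentile ranges of those distributions.
    """

    case_mean_rho: float
    case_ci: BootstrapResult
    controls_ci: BootstrapResult
    within_control_range: bool
    case_rhos: np.ndarray = field(default_factory=lambda: np.empty(0))
    pair_rhos: np.ndarray = field(default_factory=lambda: np.empty(0))


def glm_betas(
    vol: Volume4D,
    schedule: BlockSchedule,
    hrf: HRFParams = HRFParams(),
    roi: np.ndarray | None = None,
    n_digits: int = 5,
) -> np.ndarray:
    """Ordinary least-squares digit betas for one block-design run.

    The design matrix holds the five HRF-convolved digit boxcars plus an
    intercept; rest blocks form the implicit baseline.  Returns betas of
    shape (n_digits, n_voxels) — optionally restricted to a boolean ``roi``.
    """
    regs = digit_regressors(
        schedule, vol.tr, hrf, n_volumes=vol.n_volumes, n_digits=n_digits
    )
    design = np.column_stack([regs.T, np.ones(vol.n_volumes)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient design: every digit regressor must vary "
            "(an all-rest schedule cannot be fit)"
        )
    y = vol.timecourses().T  # (T, V)
    if roi is not None:
        y = y[:, np.asarray(roi, dtype=bool).ravel()]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef[:n_digits]


def stack_runs(betas_per_run: list[np.ndarray], roi=None) -> DigitPatterns:
    return DigitPatterns(betas=np.stack(betas_per_run), roi=roi)


def pattern_component_similarity(patterns: DigitPatterns) -> SimilarityMatrix:
    """Cross-validated inter-digit correlations with common-pattern removal.

    Per run the mean pattern across digits is subtracted; G[a, b] is the mean
    over ordered run pairs (i != j) of <pattern_a^i, pattern_b^j> / n_voxels,
    and r = G / sqrt(diag outer).  Cross-run products make E[G] equal the
    true common-removed second moment (run noise is independent across runs).
    """
    if patterns.n_runs < 2:
        raise ValueError("cross-validated similarity needs at least 2 runs")
    y = patterns.betas
    n_runs, n_digits, n_vox = y.shape
    if n_vox < 5 * n_digits:
        raise ValueError(
            f"ROI of {n_vox} voxels is too small for a stable "
            f"{n_digits}-condition fingerprint"
        )
    yc = y - y.mean(axis=1, keepdims=True)  # remove per-run common pattern
    g = np.zeros((n_digits, n_digits))
    n_pairs = 0
    for i in range(n_runs):
        for j in range(n_runs):
            if i == j:
                continue
            g += yc[i] @ yc[j].T / n_vox
            n_pairs += 1
    g /= n_pairs
    diag = np.diag(g).copy()
    # non-positive up to rounding noise, relative to the raw pattern power
    tol = 1e-12 * max(float(np.mean(y**2)), np.finfo(float).tiny)
    undefined = diag <= tol
    if undefined.any():
        warnings.warn(
            "non-positive estimated pattern variance for digits "
            f"{np.flatnonzero(undefined) + 1}; their correlations are NaN",
            stacklevel=2,
        )
    denom = np.sqrt(np.where(undefined, np.nan, diag))
    r = g / denom[:, None] / denom[None, :]
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(r=r, g=g, undefined=undefined)


def off_diagonal_cells(matrix: SimilarityMatrix) -> np.ndarray:
    """The 10 unique off-diagonal cells, upper-triangle order."""
    iu = np.triu_indices(matrix.r.shape[0], k=1)
    return matrix.r[iu]


def mean_overlap(matrix: SimilarityMatrix) -> float:
    """Mean of the 10 unique inter-digit cells (diagonal excluded)."""
    cells = off_diagonal_cells(matrix)
    if np.isnan(cells).any():
        warnings.warn("undefined cells present; mean overlap is NaN", stacklevel=2)
        return float("nan")
    return float(cells.mean())


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def compare_to_controls(
    case_matrix: SimilarityMatrix,
    control_matrices: list[SimilarityMatrix],
    n_iterations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ControlComparison:
    """Case fingerprint versus the control-to-control correlation distribution.

    The 10 unique cells of each fingerprint are rank-correlated (Spearman)
    across every unordered pair of controls; a bootstrap over pairs yields the
    95% range of normal inter-subject correlation.  The case's mean
    correlation with the controls (with its own bootstrap CI) is flagged as
    within or outside that range.
    """
    n = len(control_matrices)
    if n < 3:
        raise ValueError("need at least 3 control matrices")
    case = off_diagonal_cells(case_matrix)
    ctrl = np.stack([off_diagonal_cells(m) for m in control_matrices])

    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pair_rhos = np.array([_spearman(ctrl[i], ctrl[j]) for i, j in pair_idx])
    case_rhos = np.array([_spearman(case, ctrl[i]) for i in range(n)])

    rng = np.random.default_rng(seed)
    boot_pairs = pair_rhos[rng.integers(0, len(pair_rhos), size=n_iterations)]
    boot_case = case_rhos[rng.integers(0, len(case_rhos), size=n_iterations)]
    qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
    c_lo, c_hi = np.percentile(boot_pairs, qs)
    k_lo, k_hi = np.percentile(boot_case, qs)

    controls_ci = BootstrapResult(
        point=float(pair_rhos.mean()),
        ci_low=float(c_lo),
        ci_high=float(c_hi),
        n_iterations=n_iterations,
        alpha=alpha,
        seed=seed,
    )
    case_ci = BootstrapResult(
        point=float(case_rhos.mean()),
        ci_low=float(k_lo),
        ci_high=float(k_hi),
        n_iterations=n_iterations,
        alpha=alpha,
        seed=seed,
    )
    within = bool(c_lo <= case_rhos.mean() <= c_hi)
    return ControlComparison(
        case_mean_rho=float(case_rhos.mean()),
        case_ci=case_ci,
        controls_ci=controls_ci,
        within_control_range=within,
        case_rhos=case_rhos,
        pair_rhos=pair_rhos,
    )
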