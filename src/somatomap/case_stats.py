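"""Single-case inference and scalar clinical indices.

Crawford & Howell's modified t-test compares one individual's score against a
small control sample (the case is treated as a sample of one, inflating the
standard error by sqrt(1 + 1/n)).  The JZS Bayes factor is the default
Bayesian two-sample t-test: a Cauchy prior (scale 0.707 by default) on the
standardized effect size, integrated numerically; BF10 < 1/3 is conventionally
read as moderate support for the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "CaseTestResult",
    "BayesResult",
    "crawford_howell_t",
    "jzs_bayes_factor",
    "asymmetry_index",
    "phantom_magnitude",
    "amputation_level",
]


@dataclass(frozen=True)
class CaseTestResult:
    t: float
    df: int
    p: float
    tails: str


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    cauchy_scale: float
    t: float
    df: int


def crawford_howell_t(
    case_value: float, control_values, tails: str = "two"
) -> CaseTestResult:
    """Crawford-Howell t-test of one case against n controls.

    t = (case - mean) / (sd * sqrt(1 + 1/n)), df = n - 1.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    controls = np.asarray(control_values, dtype=float).ravel()
    n = controls.size
    if n < 2:
        raise ValueError("need at least 2 control values")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("control variance is zero; the test is degenerate")
    t = (case_value - controls.mean()) / (sd * np.sqrt(1.0 + 1.0 / n))
    df = n - 1
    if tails == "two":
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = stats.t.sf(abs(t), df)
    return CaseTestResult(t=float(t), df=df, p=float(min(p, 1.0)), tails=tails)


def _jzs_bf10_from_t(t: float, n1: int, n2: int, scale: float) -> float:
    """Two-sample JZS BF10 by adaptive quadrature.

    Uses the inverse-gamma mixture representation of the Cauchy prior on the
    standardized effect size: marginalizing delta analytically for fixed
    relative prior variance g leaves a one-dimensional integral over g,

        BF10 = int_0^inf (1 + N g)^(-1/2)
               [ (1 + t^2 / ((1 + N g) v)) / (1 + t^2 / v) ]^(-(v+1)/2)
               pi(g) dg,

    with N = n1 n2 / (n1 + n2), v = n1 + n2 - 2 and
    pi(g) = InverseGamma(1/2, scale^2 / 2) — numerically stable for any t.
    """
    df = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    log_null = -0.5 * (df + 1) * np.log1p(t * t / df)

    def integrand(g: float) -> float:
        shrink = 1.0 + n_eff * g
        log_alt = -0.5 * np.log(shrink) - 0.5 * (df + 1) * np.log1p(
            t * t / (shrink * df)
        )
        log_prior = (
            0.5 * np.log(scale * scale / 2.0)
            - _LOG_GAMMA_HALF
            - 1.5 * np.log(g)
            - scale * scale / (2.0 * g)
        )
        return np.exp(log_alt - log_null + log_prior)

    bf10, _ = integrate.quad(
        integrand, 0.0, np.inf, epsrel=1e-8, epsabs=0, limit=200
    )
    return bf10


_LOG_GAMMA_HALF = float(np.log(np.sqrt(np.pi)))  # log Gamma(1/2)


def jzs_bayes_factor(group_a, group_b, cauchy_scale: float = 0.707) -> BayesResult:
    """Default-prior (JZS) Bayesian two-sample t-test.

    Returns BF10, the evidence for a group difference over the null.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if cauchy_scale <= 0:
        raise ValueError("cauchy_scale must be > 0")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        raise ValueError("zero pooled variance; the test is degenerate")
    t = (a.mean() - b.mean()) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    bf10 = _jzs_bf10_from_t(float(t), n1, n2, cauchy_scale)
    return BayesResult(bf10=float(bf10), cauchy_scale=cauchy_scale, t=float(t), df=df)


def asymmetry_index(contra: float, ipsi: float) -> float:
    """Inter-hemispheric asymmetry: (contra - ipsi) / (contra + ipsi)."""
    total = contra + ipsi
    if total == 0:
        raise ValueError("asymmetry index undefined when contra + ipsi = 0")
    return (contra - ipsi) / total


def phantom_magnitude(worst_intensity: float, frequency_code: int) -> float:
    """Phantom pain/sensation magnitude: worst intensity (0-100) / frequency.

    Frequency codes: 1 = all the time, 2 = daily, 3 = weekly; the ratio
    represents the chronic aspect by combining intensity and frequency.
    """
    if not (0 <= worst_intensity <= 100):
        raise ValueError("worst_intensity must lie in [0, 100]")
    if frequency_code not in (1, 2, 3):
        raise ValueError("frequency_code must be 1, 2 or 3")
    return worst_intensity / frequency_code


def amputation_level(residual_length: float, intact_length: float) -> tuple[float, str]:
    """Residual arm length as % of the intact arm, with an anatomical label.

    41% corresponds to the elbow and 75% to the wrist; values above 41 are
    labelled 'below elbow', at or under 41 'above elbow'.
    """
    if intact_length <= 0:
        raise ValueError("intact_length must be > 0")
    if not (0 <= residual_length <= intact_length):
        raise ValueError("residual_length must lie in [0, intact_length]")
    pct = residual_length / intact_length * 100.0
    label = "below elbow" if pct > 41.0 else "above elbow"
    return pct, label
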