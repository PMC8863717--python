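"""Raw, behavioral, and bias-corrected sensory precision estimators.

Three nested estimates of response variability for one observer/condition:

raw
    Sample variance of the errors ``r - s``.  Inflated by the
    stimulus-dependent constant error a central tendency bias introduces.
behavioral
    Variance of residuals from OLS of responses on targets.  The regression
    absorbs the constant error, but shrinkage toward the range center also
    compresses responses, so this *under*-states sensory variability.
sensory
    Behavioral variance divided by the squared fitted slope.  The slope
    estimates ``1 - w_p`` (the non-shrunk fraction of the response), so the
    division corrects the compression out.  Applied conditionally: only when
    the slope is significantly below one, so unbiased data are left untouched.

`combination_test` wraps the paired one-tailed Wilcoxon signed-rank comparison
of combined-cue vs best-single-cue variability used to detect a combination
effect, with the paired Cohen's d effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import CUE1, CUE2

__all__ = [
    "RegressionFit",
    "PrecisionEstimate",
    "CombinationTestResult",
    "raw_error_variance",
    "fit_response_regression",
    "behavioral_variance",
    "sensory_variance",
    "combination_test",
    "best_single_cue",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of responses on targets: ``r = beta*s + alpha + eps``.

    ``resid_var`` uses the residual degrees of freedom (n - 2).
    ``p_beta_lt_1`` is the lower tail of ``t = (beta - 1) / se_beta`` on
    n - 2 df: the one-sided test for a slope below one, i.e. for the presence
    of a central tendency bias.
    """

    beta: float
    alpha: float
    resid_var: float
    se_beta: float
    p_beta_lt_1: float
    n: int


@dataclass(frozen=True)
class PrecisionEstimate:
    """A variance estimate of one kind: raw, behavioral, or sensory."""

    kind: str
    variance: float
    correction_applied: bool = False
    fit: RegressionFit | None = None
    degenerate: bool = False


def raw_error_variance(targets, responses) -> PrecisionEstimate:
    """Sample variance (denominator N-1) of the errors ``r - s``."""
    targets = np.asarray(targets, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if targets.shape != responses.shape:
        raise ValueError("targets and responses must have equal length")
    if targets.size < 2:
        raise ValueError(f"need at least 2 trials, got {targets.size}")
    errors = responses - targets
    return PrecisionEstimate(kind="raw", variance=float(np.var(errors, ddof=1)))


def fit_response_regression(targets, responses) -> RegressionFit:
    """Ordinary least squares of responses on targets."""
    s = np.asarray(targets, dtype=float)
    r = np.asarray(responses, dtype=float)
    if s.shape != r.shape:
        raise ValueError("targets and responses must have equal length")
    n = s.size
    if n < 3:
        raise ValueError(f"need at least 3 trials to fit the regression, got {n}")
    sxx = float(np.sum((s - s.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("all targets identical: slope is unidentifiable")
    beta = float(np.sum((s - s.mean()) * (r - r.mean())) / sxx)
    alpha = float(r.mean() - beta * s.mean())
    resid = r - (beta * s + alpha)
    resid_var = float(np.sum(resid**2) / (n - 2))
    se_beta = float(np.sqrt(resid_var / sxx))
    if se_beta == 0.0:
        p = 0.0 if beta < 1.0 else (0.5 if beta == 1.0 else 1.0)
    else:
        p = float(stats.t.cdf((beta - 1.0) / se_beta, df=n - 2))
    return RegressionFit(beta=beta, alpha=alpha, resid_var=resid_var,
                         se_beta=se_beta, p_beta_lt_1=p, n=n)


def behavioral_variance(fit: RegressionFit) -> PrecisionEstimate:
    """Behavioral precision: the variance of the regression residuals."""
    return PrecisionEstimate(kind="behavioral", variance=fit.resid_var, fit=fit)


def sensory_variance(fit: RegressionFit, alpha_level: float = 0.05) -> PrecisionEstimate:
    """Bias-corrected sensory precision: ``resid_var / beta**2``, conditionally.

    The correction is applied only when the fitted slope is significantly
    below one at ``alpha_level`` (one-sided t test); otherwise the behavioral
    variance is returned unchanged, so unbiased data are not distorted.
    A non-positive slope passing the test has no meaningful correction; the
    behavioral value is returned with ``degenerate=True`` and a warning.
    """
    significant = fit.p_beta_lt_1 < alpha_level
    if significant and fit.beta <= 0.0:
        warnings.warn(
            "fitted slope is non-positive; the slope correction is undefined "
            "and the behavioral variance is returned instead",
            RuntimeWarning,
            stacklevel=2,
        )
        return PrecisionEstimate(kind="sensory", variance=fit.resid_var,
                                 correction_applied=False, fit=fit, degenerate=True)
    if significant:
        return PrecisionEstimate(kind="sensory", variance=fit.resid_var / fit.beta**2,
                                 correction_applied=True, fit=fit)
    return PrecisionEstimate(kind="sensory", variance=fit.resid_var,
                             correction_applied=False, fit=fit)


def best_single_cue(var_cue1: float, var_cue2: float) -> str:
    """Label of the lower-variability single cue; ties go to cue 1."""
    return CUE1 if var_cue1 <= var_cue2 else CUE2


@dataclass(frozen=True)
class CombinationTestResult:
    """One-tailed paired test of combined-cue vs best-single-cue variability."""

    z: float
    p_one_tailed: float
    cohens_d: float
    pct_showing_effect: float
    n: int
    d_defined: bool = True


def combination_test(best_single_vars, combined_vars) -> CombinationTestResult:
    """Wilcoxon signed-rank test that combined variability < best-single.

    Per-observer paired variabilities; the alternative is that the combined
    condition is *less* variable (a gain in precision from fusing cues).
    Exact null distribution for n <= 25 with untied non-zero differences,
    normal approximation with continuity correction otherwise.  Paired
    Cohen's d is ``mean(best - combined) / SD(best - combined)``; when the
    differences have zero spread, d is reported as 0 with ``d_defined=False``.
    """
    best = np.asarray(best_single_vars, dtype=float)
    comb = np.asarray(combined_vars, dtype=float)
    if best.shape != comb.shape:
        raise ValueError("paired variance vectors must have equal length")
    n = best.size
    if n < 5:
        raise ValueError(f"need at least 5 paired observers, got {n}")
    diff = best - comb
    pct = float(100.0 * np.mean(diff > 0))

    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        d, d_defined = 0.0, False
    else:
        d, d_defined = float(np.mean(diff) / sd), True

    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        # no information either way
        return CombinationTestResult(z=0.0, p_one_tailed=0.5, cohens_d=d,
                                     pct_showing_effect=pct, n=n, d_defined=d_defined)
    untied = np.unique(np.abs(nonzero)).size == nonzero.size
    if n <= 25 and untied and nonzero.size == n:
        res = stats.wilcoxon(diff, alternative="greater", method="exact")
    else:
        res = stats.wilcoxon(diff, alternative="greater", method="approx", correction=True)
    p = float(res.pvalue)
    z = float(stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16)))
    return CombinationTestResult(z=z, p_one_tailed=p, cohens_d=d,
                                 pct_showing_effect=pct, n=n, d_defined=d_defined)
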