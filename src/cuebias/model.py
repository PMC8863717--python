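"""Closed-form quantities for an ideal observer with a central tendency bias.

The observer model has two stages.  First, noisy sensory estimates of a
stimulus value ``s`` are formed, one per cue, ``c_i ~ Normal(s, sigma_i**2)``,
and (when both cues are available) fused by a reliability-weighted average.
Second, the fused sensory estimate is shrunk toward the center ``mu`` of the
stimulus range by a bias weight ``w_p``, and additive response noise with SD
``sigma_n`` is applied.  The shrinkage is the central tendency
(regression-to-the-mean) bias; its weight is allowed to grow as sensory
reliability falls, which is what couples the single-cue bias weights to the
combined-cue weight ``w_pc``.

All functions accept noise levels as standard deviations (stimulus units) and
return precisions as variances (stimulus units squared).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CUE1",
    "CUE2",
    "BOTH",
    "CONDITIONS",
    "ObserverParams",
    "EffectSizes",
    "optimal_weights",
    "combined_variance",
    "combination_effect",
    "bias_weights",
    "biased_combination_effect",
    "expected_behavioral_variance",
]

#: Canonical condition labels used throughout the package.
CUE1 = "cue1"
CUE2 = "cue2"
BOTH = "both"
CONDITIONS = (CUE1, CUE2, BOTH)


def _check_sds(sigma1: float, sigma2: float) -> None:
    if not (sigma1 > 0 and sigma2 > 0):
        raise ValueError(
            f"sensory noise SDs must be positive, got sigma1={sigma1}, sigma2={sigma2}"
        )


def optimal_weights(sigma1: float, sigma2: float) -> tuple[float, float]:
    """Reliability weights of the Bayes-optimal two-cue average.

    The optimal fused estimate is ``w1*c1 + w2*c2`` with
    ``w_i = r_i / (r_1 + r_2)`` and reliability ``r_i = 1 / sigma_i**2``.

    Parameters
    ----------
    sigma1, sigma2 : float
        Standard deviations of the two cues' sensory noise (must be > 0).

    Returns
    -------
    (w1, w2) : tuple of float
        Weights on cue 1 and cue 2; they sum to one.
    """
    _check_sds(sigma1, sigma2)
    v1, v2 = sigma1 * sigma1, sigma2 * sigma2
    w1 = v2 / (v1 + v2)
    return w1, 1.0 - w1


def combined_variance(sigma1: float, sigma2: float) -> float:
    """Variance of the reliability-weighted two-cue estimate.

    ``sigma_c**2 = sigma1**2 * sigma2**2 / (sigma1**2 + sigma2**2)``, which is
    strictly below the variance of either single cue for finite SDs.
    """
    _check_sds(sigma1, sigma2)
    v1, v2 = sigma1 * sigma1, sigma2 * sigma2
    return v1 * v2 / (v1 + v2)


def combination_effect(sigma1: float, sigma2: float) -> float:
    """Maximal combination effect: the variance reduction from fusing cues.

    ``E = sigma_best**2 - sigma_c**2 = sigma_best**4 / (sigma1**2 + sigma2**2)``
    where "best" is the lower-variance cue.  The cue order given by the caller
    does not matter; the cues are relabeled internally so the best cue plays
    the role of cue 1.
    """
    _check_sds(sigma1, sigma2)
    lo = min(sigma1, sigma2)
    return lo * lo - combined_variance(sigma1, sigma2)


def bias_weights(w_pc: float, sigma1: float, sigma2: float) -> tuple[float, float]:
    """Single-cue central-bias weights implied by the combined-cue weight.

    Bayesian accounts of the central tendency bias predict the weight on the
    range center to grow as sensory reliability falls.  Given the weight
    ``w_pc`` applied on combined-cue trials (where the sensory variance is the
    fused ``sigma_c**2``), the single-cue weights are

        ``w_pi = w_pc * sigma_i**2 / (sigma_c**2 + w_pc * (sigma_i**2 - sigma_c**2))``

    which lie in ``[w_pc, 1]``: shrinkage is always at least as strong for the
    noisier single-cue estimates.
    """
    if not 0.0 <= w_pc <= 1.0:
        raise ValueError(f"w_pc must lie in [0, 1], got {w_pc}")
    _check_sds(sigma1, sigma2)
    vc = combined_variance(sigma1, sigma2)

    def one(v: float) -> float:
        return w_pc * v / (vc + w_pc * (v - vc))

    return one(sigma1 * sigma1), one(sigma2 * sigma2)


@dataclass(frozen=True)
class ObserverParams:
    """Generative ground truth for one simulated observer.

    Attributes
    ----------
    sigma1, sigma2 : float
        SDs of cue-1 and cue-2 sensory noise (stimulus units).
    sigma_n : float
        SD of additive response noise (motor noise etc.).
    w_pc : float
        Central-bias weight applied on combined-cue trials, in [0, 1].
        Single-cue bias weights are derived from it via :func:`bias_weights`.
    mu : float
        Center of the stimulus range, the shrinkage target.
    """

    sigma1: float
    sigma2: float
    sigma_n: float = 0.0
    w_pc: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        _check_sds(self.sigma1, self.sigma2)
        if self.sigma_n < 0:
            raise ValueError(f"sigma_n must be >= 0, got {self.sigma_n}")
        if not 0.0 <= self.w_pc <= 1.0:
            raise ValueError(f"w_pc must lie in [0, 1], got {self.w_pc}")

    @property
    def weights(self) -> tuple[float, float]:
        """Optimal reliability weights (w1, w2)."""
        return optimal_weights(self.sigma1, self.sigma2)

    @property
    def sigma_c_sq(self) -> float:
        """Variance of the fused sensory estimate."""
        return combined_variance(self.sigma1, self.sigma2)

    @property
    def w_p1(self) -> float:
        return bias_weights(self.w_pc, self.sigma1, self.sigma2)[0]

    @property
    def w_p2(self) -> float:
        return bias_weights(self.w_pc, self.sigma1, self.sigma2)[1]

    @property
    def best_cue(self) -> str:
        """Label of the lower-variance cue (ties go to cue 1)."""
        return CUE1 if self.sigma1 <= self.sigma2 else CUE2

    def bias_weight(self, condition: str) -> float:
        """Central-bias weight applying on trials of the given condition."""
        if condition == CUE1:
            return self.w_p1
        if condition == CUE2:
            return self.w_p2
        if condition == BOTH:
            return self.w_pc
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")

    def sensory_variance(self, condition: str) -> float:
        """Variance of the (pre-bias) sensory estimate for a condition."""
        if condition == CUE1:
            return self.sigma1 * self.sigma1
        if condition == CUE2:
            return self.sigma2 * self.sigma2
        if condition == BOTH:
            return self.sigma_c_sq
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


@dataclass(frozen=True)
class EffectSizes:
    """Sensory and behavioral (bias-attenuated) combination effects.

    ``E`` is the variance reduction an unbiased analysis would see;
    ``E_b`` is what survives in raw behavioral variances once responses are
    shrunk toward the range center.  ``E_b <= E`` whenever the bias is active,
    and it can be negative: a strong central bias can make combined-cue
    responses *more* variable relative to their own shrunken scale than
    best-single-cue responses.
    """

    E: float
    E_b: float


def biased_combination_effect(params: ObserverParams) -> EffectSizes:
    """Sensory effect ``E`` and its bias-attenuated counterpart ``E_b``.

    With the best cue relabeled as cue 1,

        ``E_b = (1 - w_p1)**2 * sigma1**2 - (1 - w_pc)**2 * sigma_c**2``

    i.e. the difference of expected behavioral variances (response noise
    cancels).  Equals ``E`` when ``w_pc = 0``.
    """
    s1, s2 = params.sigma1, params.sigma2
    if s1 > s2:  # relabel so the best cue is cue 1
        s1, s2 = s2, s1
    w_p1, _ = bias_weights(params.w_pc, s1, s2)
    vc = combined_variance(s1, s2)
    e = combination_effect(s1, s2)
    e_b = (1.0 - w_p1) ** 2 * s1 * s1 - (1.0 - params.w_pc) ** 2 * vc
    return EffectSizes(E=e, E_b=e_b)


def expected_behavioral_variance(condition: str, params: ObserverParams) -> float:
    """Expected variance of responses about their own regression line.

    For condition ``i`` this is ``(1 - w_pi)**2 * sigma_i**2 + sigma_n**2``:
    the sensory variance shrunk by the squared bias slope, plus response
    noise.  It is what the variance of OLS residuals estimates, and the
    quantity the sensory-precision correction divides by the squared slope.
    """
    w_p = params.bias_weight(condition)
    return (1.0 - w_p) ** 2 * params.sensory_variance(condition) + params.sigma_n**2
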