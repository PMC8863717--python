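"""Synthetic trial tables from the biased-observer model.

Trial tables are plain :class:`pandas.DataFrame` objects with columns
``observer_id, condition, s1, s2, target, response`` — the single interchange
format shared by the simulators, the estimators, and the CSV I/O layer.
Absent cue values (``s2`` on cue-1-only trials and vice versa) are NaN.

Randomness: every public entry point takes either an integer seed or a
:class:`numpy.random.Generator`.  Multi-observer simulations spawn one child
stream per observer/condition from a master :class:`numpy.random.SeedSequence`
so that adding observers or conditions never perturbs existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .model import BOTH, CONDITIONS, CUE1, CUE2, ObserverParams

__all__ = [
    "TRIAL_COLUMNS",
    "DesignSpec",
    "make_target_grid",
    "make_conflict_pairs",
    "simulate_trials",
    "simulate_observer",
    "fig1_params",
    "fig1_fixtures",
]

TRIAL_COLUMNS = ("observer_id", "condition", "s1", "s2", "target", "response")


def make_target_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid of target values from ``lo`` to ``hi``.

    ``make_target_grid(0.15, 0.85, 0.02)`` gives the 36-value unit-range grid
    used by the power study; ``(0.4, 0.6, 0.025)`` gives the 9-value conflict
    grid.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if step > hi - lo:
        raise ValueError(f"step {step} exceeds the range [{lo}, {hi}]")
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def make_conflict_pairs(values, include_zero_conflict: bool = False) -> np.ndarray:
    """All ordered conflicting pairs (s1, s2) from a grid of values.

    Every ordered pair with ``s1 != s2`` is returned (both orderings of each
    unordered pair), so a 9-value grid yields 72 pairs.  Zero-conflict
    self-pairs carry no information about relative cue weighting and are
    excluded by default; ``include_zero_conflict=True`` adds them back for
    robustness checks.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("need at least 2 distinct values to form conflict pairs")
    pairs = list(permutations(values, 2))
    if include_zero_conflict:
        pairs += [(v, v) for v in values]
    return np.array(pairs)


@dataclass(frozen=True)
class DesignSpec:
    """Stimulus design for one simulated experiment.

    Attributes
    ----------
    lo, hi : float
        Declared stimulus range; all targets must fall inside it.
    targets : array-like
        Target values for single-cue and congruent two-cue trials.
    reps : int
        Repetitions per target (or per conflict pair) per condition.
    conflict_pairs : array-like or None
        Ordered (s1, s2) pairs for conflict trials; None for congruent designs.
    """

    lo: float
    hi: float
    targets: np.ndarray
    reps: int = 5
    conflict_pairs: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        targets = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "targets", targets)
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if targets.min() < self.lo or targets.max() > self.hi:
            raise ValueError("target grid extends outside the declared stimulus range")
        if self.conflict_pairs is not None:
            pairs = np.asarray(self.conflict_pairs, dtype=float)
            object.__setattr__(self, "conflict_pairs", pairs)
            if pairs.min() < self.lo or pairs.max() > self.hi:
                raise ValueError("conflict pairs extend outside the declared stimulus range")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trials(
    params: ObserverParams,
    condition: str,
    *,
    targets=None,
    conflict_pairs=None,
    reps: int = 1,
    seed=None,
    observer_id: str = "obs0",
    clip_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Simulate one observer's trials for a single condition.

    Per trial, sensory estimates ``c_i ~ Normal(s_i, sigma_i**2)`` are drawn,
    fused on two-cue trials by the optimal weights, shrunk toward ``params.mu``
    by the condition's bias weight, and perturbed by response noise:

    - ``cue1``:  ``r = (1 - w_p1) * c1 + w_p1 * mu + eps``
    - ``cue2``:  ``r = (1 - w_p2) * c2 + w_p2 * mu + eps``
    - ``both``:  ``r = (1 - w_pc) * (w1*c1 + w2*c2) + w_pc * mu + eps``

    with ``eps ~ Normal(0, sigma_n**2)``.  Conflict designs pass
    ``conflict_pairs`` (only valid for ``condition="both"``); the ``target``
    column then stores the pair midpoint for bookkeeping.

    Responses are unbounded by default, matching the Gaussian model; pass
    ``clip_range`` to clamp them to an interval (this distorts variance
    recovery and is off everywhere in the shipped analyses).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if conflict_pairs is not None and condition != BOTH:
        raise ValueError("conflict pairs are only meaningful for condition='both'")
    if conflict_pairs is None and targets is None:
        raise ValueError("provide targets (congruent/single-cue) or conflict_pairs")

    rng = _as_rng(seed)

    if conflict_pairs is not None:
        pairs = np.repeat(np.asarray(conflict_pairs, dtype=float), reps, axis=0)
        s1, s2 = pairs[:, 0], pairs[:, 1]
        target = 0.5 * (s1 + s2)
    else:
        target = np.repeat(np.asarray(targets, dtype=float), reps)
        s1 = s2 = target

    n = target.size
    eps = rng.normal(0.0, params.sigma_n, n) if params.sigma_n > 0 else 0.0

    if condition == CUE1:
        c1 = rng.normal(s1, params.sigma1)
        w_p = params.w_p1
        response = (1.0 - w_p) * c1 + w_p * params.mu + eps
        s1_col, s2_col = s1, np.full(n, np.nan)
    elif condition == CUE2:
        c2 = rng.normal(s2, params.sigma2)
        w_p = params.w_p2
        response = (1.0 - w_p) * c2 + w_p * params.mu + eps
        s1_col, s2_col = np.full(n, np.nan), s2
    else:
        c1 = rng.normal(s1, params.sigma1)
        c2 = rng.normal(s2, params.sigma2)
        w1, w2 = params.weights
        fused = w1 * c1 + w2 * c2
        response = (1.0 - params.w_pc) * fused + params.w_pc * params.mu + eps
        s1_col, s2_col = s1, s2

    if clip_range is not None:
        response = np.clip(response, *clip_range)

    return pd.DataFrame(
        {
            "observer_id": observer_id,
            "condition": condition,
            "s1": s1_col,
            "s2": s2_col,
            "target": target,
            "response": np.asarray(response, dtype=float),
        }
    )


def simulate_observer(
    params: ObserverParams,
    design: DesignSpec,
    conditions=CONDITIONS,
    *,
    seed=None,
    observer_id: str = "obs0",
) -> pd.DataFrame:
    """Simulate a full experiment (several conditions) for one observer.

    One child random stream per condition is spawned from the seed, so the
    draws for any one condition do not depend on which others are requested.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(CONDITIONS))
    streams = dict(zip(CONDITIONS, children))
    frames = []
    for cond in conditions:
        rng = np.random.default_rng(streams[cond])
        if cond == BOTH and design.conflict_pairs is not None:
            frames.append(
                simulate_trials(
                    params, cond, conflict_pairs=design.conflict_pairs,
                    reps=design.reps, seed=rng, observer_id=observer_id,
                )
            )
        else:
            frames.append(
                simulate_trials(
                    params, cond, targets=design.targets,
                    reps=design.reps, seed=rng, observer_id=observer_id,
                )
            )
    return pd.concat(frames, ignore_index=True)


# Worked-example fixtures: six hypothetical observers on a degree scale.
# Sensory variances 4, 16 and 36 crossed with central-bias weight 0 or 0.5,
# no response noise, shrinkage target at the middle of a [-40, 40] range.

FIG1_VARIANCES = (4.0, 16.0, 36.0)
FIG1_BIASES = (0.0, 0.5)


def fig1_params(variance: float, bias: float) -> ObserverParams:
    """Observer parameters for one worked-example cell.

    These are single-cue observers; a far-noisier dummy second cue makes the
    fused estimate (and hence the cue-1 bias weight) coincide with cue 1, so
    ``w_p1 == bias`` exactly.
    """
    sigma = float(np.sqrt(variance))
    # With sigma2 -> inf, sigma_c -> sigma1 and w_p1 -> w_pc; use a huge but
    # finite dummy so ObserverParams stays valid.
    return ObserverParams(sigma1=sigma, sigma2=1e9, sigma_n=0.0, w_pc=bias, mu=0.0)


def fig1_fixtures(seed=None, reps: int = 2440) -> dict[tuple[float, float], pd.DataFrame]:
    """Simulate the six hypothetical observers of the worked example.

    Cue-1-only responses on a target grid from -40 to 40 in steps of 2
    (41 targets); the default ``reps`` gives just over 1e5 trials per
    observer, enough to pin the variance estimators to a few percent.

    Returns a dict keyed by ``(sensory_variance, bias_weight)``.
    """
    ss = np.random.SeedSequence(seed)
    grid = make_target_grid(-40.0, 40.0, 2.0)
    out: dict[tuple[float, float], pd.DataFrame] = {}
    cells = [(v, b) for b in FIG1_BIASES for v in FIG1_VARIANCES]
    for child, (variance, bias) in zip(ss.spawn(len(cells)), cells):
        params = fig1_params(variance, bias)
        rng = np.random.default_rng(child)
        label = f"var{variance:g}_bias{bias:g}"
        out[(variance, bias)] = simulate_trials(
            params, CUE1, targets=grid, reps=reps, seed=rng, observer_id=label
        )
    return out
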