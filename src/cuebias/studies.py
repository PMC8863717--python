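"""The two validation studies: power grids and weight-recovery grids.

Power study
    Simulated observers differ in their cue reliability ratio and the
    strength of their central tendency bias.  For each (ratio, bias, noise)
    cell a pool of observer datasets is simulated (single-cue and congruent
    two-cue trials on a unit-range target grid); random subsets of n
    observers are drawn repeatedly, per-observer variability is estimated
    with a chosen precision measure, and a one-tailed Wilcoxon signed-rank
    test compares combined-cue to best-single-cue variability.  Power is the
    fraction of subsets where the test rejects at alpha.

Recovery study
    Observers respond to conflicting cue pairs; per simulated dataset the
    weight on cue 1 is estimated both by the naive conflict regression
    (behavioral weight) and by posterior inference on the model that includes
    the bias (sensory weight).  Each grid cell reports the mean and SD of the
    estimation error for both methods.

Both studies are deterministic given their spec's master seed, and both run
at configurable scale; the shipped defaults match the full study designs
(hours of CPU) while the test suite and worked examples use reduced grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import BOTH, CUE1, CUE2, ObserverParams
from .precision import combination_test
from .simulate import make_conflict_pairs, make_target_grid, simulate_trials
from .weights import SamplerConfig, behavioral_weight_simple, fit_central_tendency_model

__all__ = [
    "MEASURES",
    "PowerGridSpec",
    "PowerGrid",
    "RecoveryGridSpec",
    "RecoveryGrid",
    "run_power_cell",
    "run_power_grid",
    "power_difference",
    "run_recovery_cell",
    "run_recovery_grid",
]

MEASURES = ("raw", "behavioral", "sensory")


@dataclass(frozen=True)
class PowerGridSpec:
    """Design of the power simulation study.

    Defaults reproduce the full study: 20 log-spaced reliability ratios in
    [1, 10], 20 log-spaced bias weights in [0.01, 1], five response-noise
    levels, sample sizes 10/20/30, 1000 simulated datasets per cell and 100
    resampled experiments per power estimate, on the 36-value unit-range
    target grid with 5 repetitions per target per condition and the best
    cue's noise fixed at sigma1 = 0.01.
    """

    ratios: tuple = tuple(np.geomspace(1.0, 10.0, 20))
    w_pcs: tuple = tuple(np.geomspace(0.01, 1.0, 20))
    sigma_ns: tuple = (0.0, 0.005, 0.01, 0.015, 0.02)
    sample_sizes: tuple = (10, 20, 30)
    n_sims: int = 1000
    n_resamples: int = 100
    measures: tuple = ("behavioral", "sensory")
    sigma1: float = 0.01
    alpha: float = 0.05
    target_lo: float = 0.15
    target_hi: float = 0.85
    target_step: float = 0.02
    reps: int = 5
    mu: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for m in self.measures:
            if m not in MEASURES:
                raise ValueError(f"unknown measure {m!r}; expected one of {MEASURES}")
        if min(self.n_sims, self.n_resamples, self.reps) < 1:
            raise ValueError("n_sims, n_resamples and reps must be >= 1")
        if any(n > self.n_sims for n in self.sample_sizes):
            raise ValueError("sample sizes cannot exceed the simulated pool size")
        if list(self.ratios) != sorted(self.ratios) or list(self.w_pcs) != sorted(self.w_pcs):
            raise ValueError("ratio and bias grids must be sorted ascending")

    @property
    def targets(self) -> np.ndarray:
        return make_target_grid(self.target_lo, self.target_hi, self.target_step)


@dataclass(frozen=True)
class PowerGrid:
    """Tidy per-cell power results plus the spec and seed that produced them."""

    table: pd.DataFrame
    spec: PowerGridSpec


_CELL_COLS = ["ratio", "w_pc", "sigma_n", "n"]


def _batch_measures(s: np.ndarray, R: np.ndarray, alpha_level: float = 0.05) -> dict:
    """Raw/behavioral/sensory variance per dataset, vectorized over rows of R."""
    n = s.size
    s_c = s - s.mean()
    sxx = float(np.sum(s_c**2))
    raw = np.var(R - s, axis=1, ddof=1)
    beta = (R - R.mean(axis=1, keepdims=True)) @ s_c / sxx
    alpha_hat = R.mean(axis=1) - beta * s.mean()
    resid = R - (beta[:, None] * s + alpha_hat[:, None])
    resid_var = np.sum(resid**2, axis=1) / (n - 2)
    se_beta = np.sqrt(resid_var / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_beta > 0, (beta - 1.0) / se_beta, np.where(beta < 1, -np.inf, np.inf))
    p_lt_1 = stats.t.cdf(t, df=n - 2)
    correct = (p_lt_1 < alpha_level) & (beta > 0)
    sensory = np.where(correct, resid_var / beta**2, resid_var)
    return {"raw": raw, "behavioral": resid_var, "sensory": sensory}


def _simulate_cell_measures(ratio, w_pc, sigma_n, spec: PowerGridSpec, rng) -> dict:
    """Per-dataset variance estimates for every condition and measure.

    Returns ``{measure: {condition: array of shape (n_sims,)}}``.
    """
    params = ObserverParams(sigma1=spec.sigma1, sigma2=ratio * spec.sigma1,
                            sigma_n=sigma_n, w_pc=w_pc, mu=spec.mu)
    s = np.repeat(spec.targets, spec.reps)
    n_trials = s.size
    w1, w2 = params.weights
    shape = (spec.n_sims, n_trials)

    def noise():
        return rng.normal(0.0, sigma_n, shape) if sigma_n > 0 else 0.0

    responses = {}
    c1 = s + rng.normal(0.0, params.sigma1, shape)
    responses[CUE1] = (1 - params.w_p1) * c1 + params.w_p1 * params.mu + noise()
    c2 = s + rng.normal(0.0, params.sigma2, shape)
    responses[CUE2] = (1 - params.w_p2) * c2 + params.w_p2 * params.mu + noise()
    c1 = s + rng.normal(0.0, params.sigma1, shape)
    c2 = s + rng.normal(0.0, params.sigma2, shape)
    responses[BOTH] = (1 - w_pc) * (w1 * c1 + w2 * c2) + w_pc * params.mu + noise()

    out: dict = {m: {} for m in MEASURES}
    for cond, R in responses.items():
        per = _batch_measures(s, R, spec.alpha)
        for m in MEASURES:
            out[m][cond] = per[m]
    return out


def _cell_power(measures: dict, n: int, spec: PowerGridSpec, rng) -> dict:
    """Power per measure from repeated size-n subsets of the dataset pool."""
    hits = {m: 0 for m in spec.measures}
    for _ in range(spec.n_resamples):
        idx = rng.choice(spec.n_sims, size=n, replace=False)
        for m in spec.measures:
            v1 = measures[m][CUE1][idx]
            v2 = measures[m][CUE2][idx]
            vc = measures[m][BOTH][idx]
            best = np.minimum(v1, v2)  # best single cue judged from the data
            res = combination_test(best, vc)
            if res.p_one_tailed < spec.alpha:
                hits[m] += 1
    return {m: hits[m] / spec.n_resamples for m in spec.measures}


def run_power_cell(ratio, w_pc, sigma_n, n, spec: PowerGridSpec, seed=None) -> dict:
    """Power of the combination test in one grid cell, per measure."""
    ss = np.random.SeedSequence(spec.seed if seed is None else seed)
    sim_ss, res_ss = ss.spawn(2)
    measures = _simulate_cell_measures(ratio, w_pc, sigma_n, spec,
                                       np.random.default_rng(sim_ss))
    return _cell_power(measures, n, spec, np.random.default_rng(res_ss))


def run_power_grid(spec: PowerGridSpec) -> PowerGrid:
    """Map the power computation over the full (ratio, bias, noise, n) grid.

    Deterministic given ``spec.seed``: each cell gets its own child random
    stream, so changing the grid extents does not perturb shared cells as
    long as the cell order up to them is unchanged.
    """
    master = np.random.SeedSequence(spec.seed)
    cells = [(r, w, sn) for sn in spec.sigma_ns for w in spec.w_pcs for r in spec.ratios]
    rows = []
    for cell_ss, (ratio, w_pc, sigma_n) in zip(master.spawn(len(cells)), cells):
        sim_ss, res_ss = cell_ss.spawn(2)
        measures = _simulate_cell_measures(ratio, w_pc, sigma_n, spec,
                                           np.random.default_rng(sim_ss))
        for n, n_ss in zip(spec.sample_sizes, res_ss.spawn(len(spec.sample_sizes))):
            powers = _cell_power(measures, n, spec, np.random.default_rng(n_ss))
            for m, p in powers.items():
                rows.append({"ratio": ratio, "w_pc": w_pc, "sigma_n": sigma_n,
                             "n": n, "measure": m, "power": p})
    return PowerGrid(table=pd.DataFrame(rows), spec=spec)


def power_difference(grid_sensory: PowerGrid, grid_behavioral: PowerGrid,
                     measure_a: str = "sensory", measure_b: str = "behavioral") -> pd.DataFrame:
    """Cellwise power gain of one measure over another (Fig.-4-style grid).

    The two grids must cover identical cells; typically they are the same
    :class:`PowerGrid` computed with both measures, or two grids run from the
    same seed (identical simulated data).
    """
    a = grid_sensory.table.query("measure == @measure_a")
    b = grid_behavioral.table.query("measure == @measure_b")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("requested measures are missing from the grids")
    merged = a.merge(b, on=_CELL_COLS, suffixes=("_a", "_b"), how="inner")
    if len(merged) != len(a) or len(merged) != len(b):
        raise ValueError("power grids do not cover identical cells")
    out = merged[_CELL_COLS].copy()
    out["power_diff"] = merged["power_a"] - merged["power_b"]
    return out


@dataclass(frozen=True)
class RecoveryGridSpec:
    """Design of the conflict weight-recovery study.

    Defaults reproduce the full study: five log-spaced reliability ratios in
    [1, 4.18], ten log-spaced bias weights in [0.01, 0.7], three noise
    levels, 100 datasets per cell, the best cue's noise at sigma1 = 0.05,
    conflict pairs from all ordered pairings of the 9-value grid 0.4..0.6
    (72 pairs) with 10 repetitions each.
    """

    ratios: tuple = tuple(np.geomspace(1.0, 4.18, 5))
    w_pcs: tuple = tuple(np.geomspace(0.01, 0.7, 10))
    sigma_ns: tuple = (0.01, 0.015, 0.02)
    n_sims: int = 100
    sigma1: float = 0.05
    conflict_lo: float = 0.4
    conflict_hi: float = 0.6
    conflict_step: float = 0.025
    reps: int = 10
    mu: float = 0.5
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seed: int | None = None

    @property
    def conflict_pairs(self) -> np.ndarray:
        grid = make_target_grid(self.conflict_lo, self.conflict_hi, self.conflict_step)
        return make_conflict_pairs(grid)


@dataclass(frozen=True)
class RecoveryGrid:
    """Tidy per-cell weight-error summaries plus the generating spec."""

    table: pd.DataFrame
    spec: RecoveryGridSpec


def run_recovery_cell(ratio, w_pc, sigma_n, spec: RecoveryGridSpec, seed=None) -> pd.DataFrame:
    """Behavioral and sensory weight errors for one (ratio, bias, noise) cell.

    Simulates ``spec.n_sims`` conflict datasets from an observer with the
    cell's parameters; for each, estimates the weight on cue 1 by the naive
    conflict regression and by the posterior fit, and returns the per-method
    mean and SD of (estimate - true w1).
    """
    params = ObserverParams(sigma1=spec.sigma1, sigma2=ratio * spec.sigma1,
                            sigma_n=sigma_n, w_pc=w_pc, mu=spec.mu)
    true_w1 = params.weights[0]
    pairs = spec.conflict_pairs
    base = spec.seed if seed is None else seed
    master = base if isinstance(base, np.random.SeedSequence) else np.random.SeedSequence(base)
    errors = {"behavioral": [], "sensory": []}
    n_nonconverged = 0
    for ds_ss in master.spawn(spec.n_sims):
        sim_ss, mcmc_ss = ds_ss.spawn(2)
        trials = simulate_trials(params, BOTH, conflict_pairs=pairs, reps=spec.reps,
                                 seed=np.random.default_rng(sim_ss))
        beh = behavioral_weight_simple(trials["s1"], trials["s2"], trials["response"])
        errors["behavioral"].append(beh.w1 - true_w1)
        cfg = replace(spec.sampler, seed=int(mcmc_ss.generate_state(1)[0] % (2**31)))
        sen = fit_central_tendency_model(trials, mu=spec.mu, config=cfg)
        errors["sensory"].append(sen.w1 - true_w1)
        if not sen.extras["converged"]:
            n_nonconverged += 1
    rows = []
    for method, errs in errors.items():
        errs = np.asarray(errs)
        rows.append({
            "ratio": ratio, "w_pc": w_pc, "sigma_n": sigma_n, "method": method,
            "mean_error": float(errs.mean()),
            "sd_error": float(errs.std(ddof=1)) if errs.size > 1 else 0.0,
            "n_sims": spec.n_sims,
            "n_nonconverged": n_nonconverged if method == "sensory" else 0,
        })
    return pd.DataFrame(rows)


def run_recovery_grid(spec: RecoveryGridSpec) -> RecoveryGrid:
    """Map the recovery computation over the (ratio, bias, noise) grid."""
    master = np.random.SeedSequence(spec.seed)
    cells = [(r, w, sn) for sn in spec.sigma_ns for w in spec.w_pcs for r in spec.ratios]
    frames = []
    for cell_ss, (ratio, w_pc, sigma_n) in zip(master.spawn(len(cells)), cells):
        frames.append(run_recovery_cell(ratio, w_pc, sigma_n, spec,
                                        seed=cell_ss))
    return RecoveryGrid(table=pd.concat(frames, ignore_index=True), spec=spec)
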