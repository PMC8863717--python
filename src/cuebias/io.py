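"""CSV trial-table I/O with validation.

The on-disk format is a plain comma-separated, UTF-8, '.'-decimal CSV with
header ``observer_id,condition,s1,s2,target,response``; absent cue values are
empty fields.  Stimulus units are whatever the experiment used — nothing is
rescaled, and callers declare the stimulus range explicitly when they want
range checking.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BOTH, CONDITIONS, CUE1, CUE2
from .simulate import TRIAL_COLUMNS

__all__ = ["read_trials_csv", "write_trials_csv", "TrialValidationError"]


class TrialValidationError(ValueError):
    """A trial table failed validation; the message carries line numbers."""


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV, preserving full float precision."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"trial table lacks columns: {missing}")
    # pandas' default float formatting is repr-based and round-trips doubles
    trials.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials_csv(
    path,
    condition_map: dict[str, str] | None = None,
    stimulus_range: tuple[float, float] | None = None,
    range_violation: str = "warn",
) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Parameters
    ----------
    path : path-like
        CSV with header; required columns ``observer_id, condition,
        response`` plus cue columns as appropriate per condition.
    condition_map : dict, optional
        Maps the file's condition labels onto the canonical
        ``cue1 / cue2 / both``.
    stimulus_range : (lo, hi), optional
        Declared range; stimulus values outside it trigger ``range_violation``
        handling ("warn", "error", or "ignore").

    Raises
    ------
    TrialValidationError
        On missing columns, missing responses, unknown condition labels, or
        condition/cue mismatches — with 1-based data line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["observer_id", "condition", "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialValidationError(f"{path}: missing required columns {missing}")
    for col in ("s1", "s2", "target"):
        if col not in df.columns:
            df[col] = np.nan

    def lines(mask) -> list[int]:
        # +2: header line plus 1-based indexing
        return [int(i) + 2 for i in df.index[mask][:10]]

    if condition_map:
        df["condition"] = df["condition"].replace(condition_map)
    unknown = ~df["condition"].isin(CONDITIONS)
    if unknown.any():
        bad = sorted(df.loc[unknown, "condition"].unique())
        raise TrialValidationError(
            f"{path}: unknown condition labels {bad} at lines {lines(unknown)}; "
            f"expected {list(CONDITIONS)} (or provide a condition_map)"
        )

    no_resp = df["response"].isna()
    if no_resp.any():
        raise TrialValidationError(f"{path}: missing responses at lines {lines(no_resp)}")

    need_s1 = df["condition"].isin([CUE1, BOTH]) & df["s1"].isna()
    if need_s1.any():
        raise TrialValidationError(f"{path}: missing s1 at lines {lines(need_s1)}")
    need_s2 = df["condition"].isin([CUE2, BOTH]) & df["s2"].isna()
    if need_s2.any():
        raise TrialValidationError(f"{path}: missing s2 at lines {lines(need_s2)}")

    no_target = df["target"].isna()
    if no_target.any():
        # single-cue and congruent trials can infer the scoring target
        df.loc[no_target, "target"] = df.loc[no_target, "s1"].fillna(df.loc[no_target, "s2"])

    if stimulus_range is not None and range_violation != "ignore":
        lo, hi = stimulus_range
        stim = df[["s1", "s2"]].to_numpy(dtype=float)
        out = (np.nan_to_num(stim, nan=lo) < lo) | (np.nan_to_num(stim, nan=lo) > hi)
        if out.any():
            msg = (f"{path}: stimulus values outside declared range [{lo}, {hi}] "
                   f"at lines {lines(out.any(axis=1))}")
            if range_violation == "error":
                raise TrialValidationError(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)

    return df.loc[:, list(TRIAL_COLUMNS)]
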