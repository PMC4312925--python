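"""Optional BOLD-timeseries path: forward simulation and single-trial GLM.

The forward model convolves each trial's (instantaneous) onset with the
canonical double-gamma hemodynamic response, scaled by that trial's voxel
amplitudes, within run boundaries. The inverse path re-estimates one
amplitude per trial per voxel by ordinary least squares with one convolved
regressor per trial plus per-run intercept and linear-drift columns, i.e. a
beta-series ("each trial its own regressor") estimator. In the noiseless
case the two are exact inverses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import PatternMatrix, as_matrix, validate_trial_table
from .exceptions import AlignmentError, ConfigurationError, EstimationError

__all__ = [
    "canonical_hrf",
    "simulate_timeseries",
    "estimate_single_trial_amplitudes",
]

# Canonical double-gamma parameters (response peak ~5 s, undershoot ~15 s,
# undershoot 1/6 of the peak lobe), peak-normalized to 1.
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_DISPERSION = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response at times ``t`` (s).

    Zero for ``t <= 0``; normalized so the positive peak equals 1.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, _PEAK_DELAY / _DISPERSION, scale=_DISPERSION)
    h = h - _UNDERSHOOT_RATIO * gamma.pdf(
        t, _UNDERSHOOT_DELAY / _DISPERSION, scale=_DISPERSION
    )
    h = np.where(t > 0, h, 0.0)
    grid = np.linspace(0.0, 32.0, 3201)
    peak = np.max(
        gamma.pdf(grid, _PEAK_DELAY, scale=_DISPERSION)
        - _UNDERSHOOT_RATIO * gamma.pdf(grid, _UNDERSHOOT_DELAY, scale=_DISPERSION)
    )
    return h / peak


def _scan_times(tr_s: float, run_duration_s: float) -> np.ndarray:
    n_scans = int(np.floor(run_duration_s / tr_s))
    return np.arange(n_scans) * tr_s


def simulate_timeseries(
    trials: pd.DataFrame,
    amplitudes: PatternMatrix | np.ndarray,
    tr_s: float = 2.5,
    run_duration_s: float = 387.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Voxel-by-scan BOLD matrix from trial onsets and amplitudes.

    Scans are ordered run by run; each run contributes
    ``floor(run_duration_s / tr_s)`` scans and trials never spill across run
    boundaries (the response is evaluated only within its own run).
    """
    validate_trial_table(trials)
    if "onset_s" not in trials.columns:
        raise ConfigurationError("trial table has no onset_s column; "
                                 "simulate with with_onsets=True")
    A = as_matrix(amplitudes)
    if A.shape[1] != len(trials):
        raise AlignmentError(
            f"amplitude matrix has {A.shape[1]} columns for {len(trials)} trials"
        )
    times = _scan_times(tr_s, run_duration_s)
    run_ids = sorted(trials["run_id"].unique())
    n_vox = A.shape[0]
    Y = np.zeros((n_vox, len(times) * len(run_ids)))
    for k, run_id in enumerate(run_ids):
        run = trials[trials["run_id"] == run_id]
        if (run["onset_s"] > run_duration_s).any():
            raise ConfigurationError(
                f"run {run_id} has onsets beyond run_duration_s={run_duration_s}"
            )
        block = slice(k * len(times), (k + 1) * len(times))
        for j, onset in zip(run.index, run["onset_s"]):
            h = canonical_hrf(times - float(onset))
            Y[:, block] += np.outer(A[:, j], h)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Y = Y + rng.normal(0.0, noise_sd, size=Y.shape)
    return Y


def _design_matrix(
    trials: pd.DataFrame, tr_s: float, run_duration_s: float
) -> tuple[np.ndarray, list[int]]:
    """One convolved regressor per trial + per-run intercept and drift."""
    times = _scan_times(tr_s, run_duration_s)
    run_ids = sorted(trials["run_id"].unique())
    n_scans = len(times) * len(run_ids)
    n_trials = len(trials)
    X = np.zeros((n_scans, n_trials + 2 * len(run_ids)))
    trial_cols = list(range(n_trials))
    for k, run_id in enumerate(run_ids):
        run = trials[trials["run_id"] == run_id]
        block = slice(k * len(times), (k + 1) * len(times))
        for j, onset in zip(run.index, run["onset_s"]):
            X[block, j] = canonical_hrf(times - float(onset))
        X[block, n_trials + 2 * k] = 1.0
        X[block, n_trials + 2 * k + 1] = np.linspace(-1.0, 1.0, len(times))
    return X, trial_cols


def estimate_single_trial_amplitudes(
    timeseries: np.ndarray,
    trials: pd.DataFrame,
    tr_s: float = 2.5,
    run_duration_s: float = 387.5,
) -> PatternMatrix:
    """OLS beta-series estimates, one amplitude per trial per voxel.

    Raises
    ------
    EstimationError
        If the design is rank deficient, naming the trial pairs whose
        regressors are (near-)collinear.
    """
    validate_trial_table(trials)
    if "onset_s" not in trials.columns:
        raise ConfigurationError("trial table has no onset_s column")
    Y = np.asarray(timeseries, dtype=float)
    X, trial_cols = _design_matrix(trials, tr_s, run_duration_s)
    if Y.shape[1] != X.shape[0]:
        raise AlignmentError(
            f"timeseries has {Y.shape[1]} scans but the design expects {X.shape[0]}"
        )
    offenders = _collinear_trials(X, trial_cols, trials)
    if offenders or np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(
            "rank-deficient or unestimable single-trial design"
            + (f"; near-collinear trial pairs: {offenders}" if offenders else "")
        )
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return PatternMatrix(beta[trial_cols].T)


def _collinear_trials(X, trial_cols, trials) -> list[tuple[int, int]]:
    G = X[:, trial_cols]
    norms = np.linalg.norm(G, axis=0)
    norms[norms == 0] = 1.0
    C = (G / norms).T @ (G / norms)
    ids = trials["trial_id"].to_numpy()
    out = []
    for i in range(len(trial_cols)):
        for j in range(i + 1, len(trial_cols)):
            if abs(C[i, j]) > 0.9999:
                out.append((int(ids[i]), int(ids[j])))
    return out
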