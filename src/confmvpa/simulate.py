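"""Synthetic multi-subject generator for voxel-by-trial retrieval data.

The generator emulates an event-related source-memory experiment: three
retrieval conditions (spatial, temporal, pair), a fixed number of trials per
condition distributed as evenly as possible over runs, per-condition
response-time distributions, and a configurable fraction of
incorrect/forgotten trials.

Amplitudes follow an additive model per voxel ``v`` and trial ``t``::

    D[v, t] = baseline
              + mean_offset[cond(t)]
              + pattern_effect * w_cond(t)[v]
              + rt_coupling * (RT_t - mean RT) * g[v]
              + noise,   noise ~ N(0, noise_sd^2) i.i.d.

where each ``w_cond`` is a fixed per-subject voxel pattern, zero-mean and
unit-norm across voxels (so patterns never move the spatial mean), and ``g``
is the uniform unit-norm loading (RT effects are a global gain by design:
exactly the confound that response-time residualization is meant to remove).
The injected ground truth is returned alongside the matrix so that recovery
can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RT_TRUNCATION_MS, SimulationConfig
from .data import CONDITIONS, PatternMatrix, validate_trial_table
from .exceptions import ConfigurationError

__all__ = [
    "GroundTruth",
    "simulate_trial_table",
    "simulate_patterns",
    "simulate_subject",
    "subject_seeds",
]


def subject_seeds(seed: int, n_subjects: int) -> np.ndarray:
    """Derive one reproducible 31-bit seed per subject from a master seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n_subjects)


def simulate_trial_table(
    config: SimulationConfig,
    subject_seed: int,
    with_onsets: bool = False,
) -> pd.DataFrame:
    """Generate one subject's trial table.

    Trials of each condition are dealt round-robin over runs, then shuffled
    within run. Response times are truncated-normal (lower bound 200 ms)
    with the configured per-condition mean/sd; a Bernoulli
    ``incorrect_rate`` fraction of trials is flagged incorrect. With
    ``with_onsets=True``, onsets are laid out within each run with jittered
    inter-trial fixation intervals drawn from a truncated exponential on
    ``[min_jitter_s, max_jitter_s]``.
    """
    rng = np.random.default_rng([int(subject_seed), 0])
    n_per = config.trials_per_condition
    n_runs = config.n_runs

    rows = []
    for cond in CONDITIONS:
        runs = (np.arange(n_per) % n_runs) + 1
        lo = (RT_TRUNCATION_MS - config.rt_means[cond]) / config.rt_sds[cond]
        rt = stats.truncnorm.rvs(
            lo, np.inf, loc=config.rt_means[cond], scale=config.rt_sds[cond],
            size=n_per, random_state=rng,
        )
        for r, t in zip(runs, rt):
            rows.append((cond, float(t), int(r)))

    df = pd.DataFrame(rows, columns=["condition", "response_time_ms", "run_id"])
    # shuffle presentation order within each run
    order = np.concatenate([
        rng.permutation(np.flatnonzero(df["run_id"].to_numpy() == r))
        for r in range(1, n_runs + 1)
    ])
    df = df.iloc[order].reset_index(drop=True)
    df["correct"] = rng.random(len(df)) >= config.incorrect_rate
    df.insert(0, "trial_id", np.arange(len(df)))

    if with_onsets:
        df["onset_s"] = _assign_onsets(df, config, rng)
    return validate_trial_table(df)


def _assign_onsets(df: pd.DataFrame, config: SimulationConfig, rng) -> np.ndarray:
    """Jittered onsets per run; errors if the run cannot hold its trials."""
    lo, hi = config.min_jitter_s, config.max_jitter_s
    scale = 3.0  # mean fixation well inside [0.5, 13] for realistic pacing
    onsets = np.empty(len(df))
    for run_id, run in df.groupby("run_id", sort=True):
        t = 0.0
        for i in run.index:
            b = (hi - lo) / scale
            t += stats.truncexpon.rvs(b, loc=lo, scale=scale, random_state=rng)
            onsets[i] = t
            t += config.trial_duration_s
        if t > config.run_duration_s:
            raise ConfigurationError(
                f"run {run_id} needs {t:.1f} s but run_duration_s is "
                f"{config.run_duration_s:.1f}; reduce trials or lengthen runs"
            )
    return onsets


@dataclass
class GroundTruth:
    """Injected signal components of one simulated subject."""

    condition_patterns: dict[str, np.ndarray]  # zero-mean unit-norm, per voxel
    rt_loading: np.ndarray                     # uniform unit-norm, per voxel
    mean_offsets: dict[str, float]
    baseline: float
    clean: np.ndarray                          # noise-free voxel-by-trial matrix


def simulate_patterns(
    config: SimulationConfig,
    trials: pd.DataFrame,
    subject_seed: int,
) -> tuple[PatternMatrix, GroundTruth]:
    """Generate one subject's voxel-by-trial amplitude matrix.

    Returns the matrix together with the :class:`GroundTruth` components
    actually injected, for oracle tests and parameter-recovery checks.
    """
    validate_trial_table(trials)
    rng = np.random.default_rng([int(subject_seed), 1])
    n_vox, n_trials = config.n_voxels, len(trials)

    patterns: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        w = rng.standard_normal(n_vox)
        w -= w.mean()
        norm = np.linalg.norm(w)
        patterns[cond] = w / norm if norm > 0 else w
    g = np.full(n_vox, 1.0 / np.sqrt(n_vox))

    cond = trials["condition"].to_numpy()
    rt = trials["response_time_ms"].to_numpy(dtype=float)
    rt_dev = rt - rt.mean()

    clean = np.full((n_vox, n_trials), config.baseline)
    for c in CONDITIONS:
        cols = cond == c
        clean[:, cols] += config.mean_offsets[c]
        clean[:, cols] += config.pattern_effect * patterns[c][:, None]
    clean += config.rt_coupling * g[:, None] * rt_dev[None, :]

    values = clean.copy()
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    truth = GroundTruth(
        condition_patterns=patterns,
        rt_loading=g,
        mean_offsets=dict(config.mean_offsets),
        baseline=config.baseline,
        clean=clean,
    )
    return PatternMatrix(values), truth


def simulate_subject(
    config: SimulationConfig,
    subject_seed: int,
    with_onsets: bool = False,
) -> tuple[pd.DataFrame, PatternMatrix, GroundTruth]:
    """Trial table plus amplitude matrix for one subject (one seed)."""
    trials = simulate_trial_table(config, subject_seed, with_onsets=with_onsets)
    D, truth = simulate_patterns(config, trials, subject_seed)
    return trials, D, truth
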