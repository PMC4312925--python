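"""Group-level inference: one-sample t versus chance, permutation null.

Subject-level held-out accuracies are summarized by a one-sample t statistic
against the 50% binary chance level. Significance is assessed by a
label-permutation test: in each permutation every subject's condition labels
are shuffled among that subject's correct trials (class counts preserved,
labels never cross subjects), the entire per-subject scheme — balancing,
splitting, C selection, final fit, held-out scoring — is re-run, and the
group t is recomputed. The one-sided p-value uses the add-one estimator
``p = (1 + #{perm t >= observed t}) / (1 + n_perm)``, so p is never zero.

Because neither projection correction depends on condition labels, corrected
feature matrices are computed once per subject and reused across
permutations; only the label vector is re-drawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import _decode
from .config import ClassifierSpec
from .data import PatternMatrix, as_matrix, validate_trial_table
from .exceptions import ConfmvpaError, DataError
from .projection import apply_correction

__all__ = ["GroupResult", "group_t", "permutation_test"]

CHANCE = 0.5


def group_t(
    accuracies: np.ndarray, chance: float = CHANCE
) -> tuple[float, float, float, int]:
    """One-sample t of subject accuracies versus chance.

    Returns ``(mean, sem, t, df)``. With zero variance across subjects the
    statistic is undefined: returns signed infinity (with a warning) when
    the mean differs from chance, else ``t = 0``.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise DataError("group t needs at least 2 subjects")
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    df = acc.size - 1
    sem = sd / np.sqrt(acc.size)
    if sd == 0.0:
        if mean == chance:
            return mean, 0.0, 0.0, df
        warnings.warn("zero variance across subjects; t is infinite")
        return mean, 0.0, float(np.sign(mean - chance) * np.inf), df
    return mean, float(sem), float((mean - chance) / sem), df


@dataclass
class GroupResult:
    """Group decoding summary plus its permutation null."""

    mean_accuracy: float
    sem: float
    t_value: float
    df: int
    n_permutations: int
    perm_t_values: np.ndarray
    p_value: float
    significant: bool
    alpha: float = 0.05
    accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sem": self.sem,
            "t_value": self.t_value,
            "df": self.df,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "accuracies": np.asarray(self.accuracies).tolist(),
        }


def _prepare_subject(D, trials, spec, correction):
    """Corrected features + labels/runs for a subject's correct trials."""
    validate_trial_table(trials)
    V = as_matrix(D)
    if V.shape[1] != len(trials):
        raise DataError("matrix/trial-table misalignment")
    correct = trials["correct"].to_numpy(dtype=bool)
    idx = np.flatnonzero(correct)
    if idx.size == 0:
        raise DataError("subject has no correct trials")
    sub = trials.iloc[idx].reset_index(drop=True)
    X = apply_correction(V[:, idx], sub, correction).values.T
    cond = sub["condition"].to_numpy()
    runs = sub["run_id"].to_numpy()
    return X, cond, runs


def _evaluate(X, cond, runs, target, rng, spec, tune, fixed_c, standardize, loss):
    y = cond == target
    if y.all() or not y.any():
        raise DataError(f"one class empty for target {target!r}")
    res = _decode(
        X, y, runs, rng, c_grid=spec.c_grid, n_folds=spec.n_folds,
        train_fraction=spec.train_fraction, standardize=standardize,
        loss=loss, tune=tune, fixed_c=fixed_c,
    )
    return res["accuracy"]


def permutation_test(
    subjects,
    spec: ClassifierSpec | None = None,
    correction: str | None = None,
    n_perm: int = 3000,
    seed: int = 0,
    *,
    alpha: float = 0.05,
    tune: str = "cv",
    fixed_c: float = 0.001,
    standardize: bool = True,
    loss: str = "squared_hinge",
) -> GroupResult:
    """Group permutation test over a list of ``(matrix, trial_table)`` pairs.

    ``tune="fixed"`` is the fast mode: the same fixed C is used for the
    observed statistic and every permutation, preserving exchangeability
    while avoiding the per-permutation grid search.
    """
    spec = spec or ClassifierSpec()
    if len(subjects) < 2:
        raise DataError("permutation test needs at least 2 subjects")
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    prepared = [
        _prepare_subject(D, trials, spec, correction) for D, trials in subjects
    ]
    master = np.random.default_rng(seed)
    subject_rngs = [
        np.random.default_rng(int(s))
        for s in master.integers(0, 2**31 - 1, size=len(prepared))
    ]
    kwargs = dict(tune=tune, fixed_c=fixed_c, standardize=standardize, loss=loss)

    observed = np.array([
        _evaluate(X, cond, runs, spec.target_condition, rng, spec, **kwargs)
        for (X, cond, runs), rng in zip(prepared, subject_rngs)
    ])
    mean, sem, t_obs, df = group_t(observed)

    perm_t = np.empty(n_perm)
    for p in range(n_perm):
        try:
            accs = np.empty(len(prepared))
            for s, ((X, cond, runs), rng) in enumerate(
                zip(prepared, subject_rngs)
            ):
                shuffled = rng.permutation(cond)
                accs[s] = _evaluate(
                    X, shuffled, runs, spec.target_condition, rng, spec,
                    **kwargs,
                )
            perm_t[p] = group_t(accs)[2]
        except ConfmvpaError as err:
            raise DataError(f"permutation {p} failed: {err}") from err

    p_value = float((1 + np.sum(perm_t >= t_obs)) / (1 + n_perm))
    return GroupResult(
        mean_accuracy=mean,
        sem=sem,
        t_value=t_obs,
        df=df,
        n_permutations=n_perm,
        perm_t_values=perm_t,
        p_value=p_value,
        significant=p_value <= alpha,
        alpha=alpha,
        accuracies=observed,
    )
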