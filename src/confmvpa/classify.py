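"""Per-subject binary decoding of one retrieval condition versus the rest.

The scheme mirrors a within-subject ROI decoding analysis: correct trials
are labeled target versus non-target, the larger class is randomly
down-sampled to balance training classes, trials are split 80/20 into
training and held-out test sets (stratified by class), the linear-SVM
regularization parameter C is chosen by cross-validation whose folds follow
run boundaries within the training set, and the final model — trained on
the full training set at the chosen C — is scored once on the untouched
test set. Feature standardization is estimated on training trials only.

:class:`SubjectDecoder` packages the scheme as a scikit-learn-style
estimator; :func:`classify_subject` is the domain-level wrapper taking a
voxel-by-trial matrix and a trial table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .config import DEFAULT_C_GRID, ClassifierSpec
from .data import CONDITIONS, PatternMatrix, as_matrix, validate_trial_table
from .exceptions import DataError, TuningError
from .projection import apply_correction

__all__ = [
    "SubjectDecoder",
    "SubjectResult",
    "select_trials",
    "downsample_balance",
    "split_train_test",
    "tune_c",
    "classify_subject",
]


def select_trials(trials: pd.DataFrame, target: str) -> tuple[np.ndarray, np.ndarray]:
    """Indices of correct trials and their binary labels (target vs rest).

    Returns ``(idx, y)`` where ``idx`` are positional indices into the trial
    table (equivalently columns of the aligned matrix) and ``y`` is True for
    the target condition.
    """
    validate_trial_table(trials)
    if target not in CONDITIONS:
        raise DataError(f"target must be one of {CONDITIONS}, got {target!r}")
    correct = trials["correct"].to_numpy(dtype=bool)
    idx = np.flatnonzero(correct)
    if idx.size == 0:
        raise DataError("no correct trials to classify")
    y = trials["condition"].to_numpy()[idx] == target
    if y.all() or not y.any():
        raise DataError(
            f"one class is empty for target {target!r} among correct trials"
        )
    return idx, y


def downsample_balance(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Positions keeping all of the smaller class and a random subsample of
    the larger, without replacement; order is sorted for determinism."""
    y = np.asarray(y, dtype=bool)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    if pos.size == 0 or neg.size == 0:
        raise DataError("both classes must be non-empty before balancing")
    n = min(pos.size, neg.size)
    if pos.size > n:
        pos = rng.choice(pos, size=n, replace=False)
    if neg.size > n:
        neg = rng.choice(neg, size=n, replace=False)
    return np.sort(np.concatenate([pos, neg]))


def split_train_test(
    y: np.ndarray,
    train_fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split: positions of train and test members.

    Each class is permuted independently and cut at
    ``round(train_fraction * n_class)``; a class left without train or test
    members is a data error.
    """
    y = np.asarray(y, dtype=bool)
    train_parts, test_parts = [], []
    for cls in (True, False):
        members = np.flatnonzero(y == cls)
        n_train = int(round(train_fraction * members.size))
        if n_train < 1 or n_train >= members.size:
            raise DataError(
                f"train_fraction={train_fraction} leaves class {cls} without "
                "train or test trials"
            )
        perm = rng.permutation(members)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return (
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
    )


def _fit_svm(X, y, C, loss, seed):
    dual = loss == "hinge"
    clf = LinearSVC(C=C, loss=loss, dual=dual, max_iter=2000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def _standardize_params(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _run_folds(runs: np.ndarray, n_folds: int) -> list[np.ndarray]:
    """Fold membership by run: one fold per run when possible, otherwise
    contiguous runs grouped as evenly as possible."""
    unique = np.unique(runs)
    groups = np.array_split(unique, min(n_folds, unique.size))
    return [np.flatnonzero(np.isin(runs, g)) for g in groups if g.size]


def tune_c(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    c_grid=DEFAULT_C_GRID,
    n_folds: int = 5,
    standardize: bool = True,
    loss: str = "squared_hinge",
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Run-wise cross-validated choice of C over the grid.

    Returns ``(chosen_c, fold_accuracies)`` with fold accuracies of shape
    ``(len(c_grid), n_folds_used)``; NaN marks a degenerate fold (training
    part single-class). Ties break toward the smallest C.
    """
    folds = _run_folds(np.asarray(runs), n_folds)
    if len(folds) < 2:
        raise TuningError("need at least 2 run-folds to cross-validate C")
    c_grid = list(c_grid)
    acc = np.full((len(c_grid), len(folds)), np.nan)
    for k, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        ytr, yva = y[train_idx], y[val_idx]
        if np.unique(ytr).size < 2:
            warnings.warn(f"fold {k}: training part single-class; skipped")
            continue
        if np.unique(yva).size < 2:
            warnings.warn(f"fold {k}: validation part single-class; scoring "
                          "on available labels")
        Xtr, Xva = X[train_idx], X[val_idx]
        if standardize:
            mu, sd = _standardize_params(Xtr)
            Xtr, Xva = (Xtr - mu) / sd, (Xva - mu) / sd
        for i, C in enumerate(c_grid):
            clf = _fit_svm(Xtr, ytr, C, loss, seed)
            acc[i, k] = float(np.mean(clf.predict(Xva) == yva))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(acc, axis=1)
    if np.all(np.isnan(means)):
        raise TuningError("all cross-validation folds degenerate")
    best = np.nanmax(means)
    chosen = c_grid[int(np.flatnonzero(means >= best - 1e-12)[0])]
    return float(chosen), acc


def _decode(
    X: np.ndarray,
    y: np.ndarray,
    runs: np.ndarray,
    rng: np.random.Generator,
    *,
    c_grid=DEFAULT_C_GRID,
    n_folds: int = 5,
    train_fraction: float = 0.8,
    standardize: bool = True,
    loss: str = "squared_hinge",
    tune: str = "cv",
    fixed_c: float = 0.001,
    keep_model: bool = False,
) -> dict:
    """Balance -> split -> (tune) -> final fit -> held-out accuracy.

    ``X`` is (n_trials, n_voxels) restricted to correct trials, ``y`` the
    binary labels, ``runs`` the run ids. This is the hot path shared by the
    estimator and the permutation loop.
    """
    keep = downsample_balance(y, rng)
    Xb, yb, rb = X[keep], y[keep], runs[keep]
    tr, te = split_train_test(yb, train_fraction, rng)
    svm_seed = int(rng.integers(2**31 - 1))
    fold_acc = None
    if tune == "cv":
        chosen_c, fold_acc = tune_c(
            Xb[tr], yb[tr], rb[tr], c_grid=c_grid, n_folds=n_folds,
            standardize=standardize, loss=loss, seed=svm_seed,
        )
    elif tune == "fixed":
        chosen_c = float(fixed_c)
    else:
        raise ValueError(f"unknown tune mode {tune!r}")
    Xtr, Xte = Xb[tr], Xb[te]
    if standardize:
        mu, sd = _standardize_params(Xtr)
        Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    clf = _fit_svm(Xtr, yb[tr], chosen_c, loss, svm_seed)
    accuracy = float(np.mean(clf.predict(Xte) == yb[te]))
    out = {
        "accuracy": accuracy,
        "chosen_c": chosen_c,
        "fold_accuracies": fold_acc,
        "n_train_per_class": int(yb[tr].sum()),
        "n_test_per_class": int(yb[te].sum()),
        "balanced_positions": keep,
        "train_positions": tr,
        "test_positions": te,
    }
    if keep_model:
        out["model"] = clf
        out["scale_"] = (mu, sd)
    return out


class SubjectDecoder(BaseEstimator):
    """One subject's confound-aware decoding scheme as an estimator.

    Parameters
    ----------
    target_condition
        Condition decoded against the other two.
    correction
        ``None``/"none", "mean_signal" or "response_time"; applied to the
        correct-trial matrix before any training (see ``correction_scope``).
    c_grid, n_folds, train_fraction
        Regularization grid (decades 1e-10..1 by default), number of
        run-wise CV folds, and train share of the balanced set.
    standardize
        Per-voxel z-scoring with training-set statistics.
    loss
        "squared_hinge" (LIBLINEAR's default L2-loss SVC, primal) or
        "hinge" (dual).
    tune
        "cv" for the cross-validated C search, "fixed" to use ``fixed_c``.
    correction_scope
        "all": estimate the projection from all correct trials (the default
        analysis choice); "train": estimate from training trials only and
        apply to both partitions (no test-set influence on the projector).
    random_state
        Seed for down-sampling, splitting and the SVM solver.

    Attributes (after ``fit``)
    --------------------------
    accuracy_, chosen_c_, fold_accuracies_, n_train_per_class_,
    n_test_per_class_, classes_, coef_, intercept_
    """

    def __init__(
        self,
        target_condition: str = "pair",
        correction: str | None = None,
        c_grid=DEFAULT_C_GRID,
        n_folds: int = 5,
        train_fraction: float = 0.8,
        standardize: bool = True,
        loss: str = "squared_hinge",
        tune: str = "cv",
        fixed_c: float = 0.001,
        correction_scope: str = "all",
        random_state: int | None = None,
    ):
        self.target_condition = target_condition
        self.correction = correction
        self.c_grid = c_grid
        self.n_folds = n_folds
        self.train_fraction = train_fraction
        self.standardize = standardize
        self.loss = loss
        self.tune = tune
        self.fixed_c = fixed_c
        self.correction_scope = correction_scope
        self.random_state = random_state

    def fit(self, X, y, *, rt=None, runs=None, correct=None):
        """Run the full scheme.

        Parameters
        ----------
        X : (n_trials, n_voxels)
            Trial-by-voxel amplitude matrix (all trials).
        y : (n_trials,)
            Condition labels.
        rt, runs, correct
            Per-trial response times (ms), run ids, and correctness flags;
            ``correct`` defaults to all-True, ``runs`` to a single run.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n = X.shape[0]
        if y.shape[0] != n:
            raise DataError("X and y disagree on the number of trials")
        if rt is None and self.correction == "response_time":
            raise DataError("response_time correction requires rt")
        rt = np.asarray(rt, dtype=float) if rt is not None else None
        runs = np.asarray(runs) if runs is not None else np.ones(n, dtype=int)
        correct = (
            np.asarray(correct, dtype=bool) if correct is not None
            else np.ones(n, dtype=bool)
        )
        trials = pd.DataFrame({
            "trial_id": np.arange(n),
            "condition": y,
            "response_time_ms": rt if rt is not None else np.ones(n),
            "run_id": runs,
            "correct": correct,
        })
        idx, yb = select_trials(trials, self.target_condition)
        Xc = _corrected_features(
            X, trials, idx, self.correction, self.correction_scope,
        )
        rng = np.random.default_rng(self.random_state)
        res = _decode(
            Xc, yb, runs[idx], rng,
            c_grid=self.c_grid, n_folds=self.n_folds,
            train_fraction=self.train_fraction, standardize=self.standardize,
            loss=self.loss, tune=self.tune, fixed_c=self.fixed_c,
            keep_model=True,
        )
        self.accuracy_ = res["accuracy"]
        self.chosen_c_ = res["chosen_c"]
        self.fold_accuracies_ = res["fold_accuracies"]
        self.n_train_per_class_ = res["n_train_per_class"]
        self.n_test_per_class_ = res["n_test_per_class"]
        self.classes_ = np.array([False, True])
        # positions are into the correct-trial subset; map back to raw trials
        self.correct_indices_ = idx
        self.balanced_trials_ = idx[res["balanced_positions"]]
        self.train_trials_ = self.balanced_trials_[res["train_positions"]]
        self.test_trials_ = self.balanced_trials_[res["test_positions"]]
        self._svm = res["model"]
        self._mu, self._sd = res["scale_"]
        self.coef_ = self._svm.coef_
        self.intercept_ = self._svm.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Predict target membership for trial-by-voxel features.

        ``X`` must live in the same (corrected) feature space the model was
        trained in; standardization uses the stored training statistics.
        """
        check_is_fitted(self, "_svm")
        X = np.asarray(X, dtype=float)
        return self._svm.predict((X - self._mu) / self._sd)

    def score(self, X, y):
        y = np.asarray(y)
        truth = y == self.target_condition if y.dtype.kind in "UO" else y.astype(bool)
        return float(np.mean(self.predict(X) == truth))


def _corrected_features(X, trials, idx, correction, scope):
    """Correct the correct-trial submatrix; rows trials, columns voxels."""
    sub = trials.iloc[idx].reset_index(drop=True)
    D_sub = X[idx].T  # voxel-by-trial for the projection operators
    if correction in (None, "none") or scope == "all":
        return apply_correction(D_sub, sub, correction).values.T
    if scope != "train":
        raise ValueError(f"unknown correction_scope {scope!r}")
    # train-scope needs the split, which lives inside _decode
    raise NotImplementedError(
        "correction_scope='train' is available via classify_subject"
    )


@dataclass
class SubjectResult:
    """Held-out decoding outcome for one subject."""

    accuracy: float
    chosen_c: float
    n_train_per_class: int
    n_test_per_class: int
    fold_accuracies: np.ndarray | None
    c_grid: tuple[float, ...]
    target_condition: str
    correction: str | None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "chosen_c": self.chosen_c,
            "n_train_per_class": self.n_train_per_class,
            "n_test_per_class": self.n_test_per_class,
            "fold_accuracies": None if self.fold_accuracies is None
            else np.asarray(self.fold_accuracies).tolist(),
            "c_grid": list(self.c_grid),
            "target_condition": self.target_condition,
            "correction": self.correction,
        }


def classify_subject(
    D: PatternMatrix | np.ndarray,
    trials: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    correction: str | None = None,
    seed: int | None = None,
    *,
    tune: str = "cv",
    fixed_c: float = 0.001,
    standardize: bool = True,
    loss: str = "squared_hinge",
    correction_scope: str = "all",
) -> SubjectResult:
    """Full per-subject scheme on a voxel-by-trial matrix and trial table."""
    spec = spec or ClassifierSpec()
    V = as_matrix(D)
    if V.shape[1] != len(trials):
        raise DataError(
            f"matrix has {V.shape[1]} trial columns for {len(trials)} trials"
        )
    validate_trial_table(trials)
    idx, y = select_trials(trials, spec.target_condition)
    sub = trials.iloc[idx].reset_index(drop=True)
    runs = sub["run_id"].to_numpy()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    if correction_scope == "all" or correction in (None, "none"):
        Xc = apply_correction(V[:, idx], sub, correction).values.T
        res = _decode(
            Xc, y, runs, rng, c_grid=spec.c_grid, n_folds=spec.n_folds,
            train_fraction=spec.train_fraction, standardize=standardize,
            loss=loss, tune=tune, fixed_c=fixed_c,
        )
    elif correction_scope == "train":
        res = _decode_train_scope(
            V, sub, idx, y, runs, rng, spec, correction,
            standardize=standardize, loss=loss, tune=tune, fixed_c=fixed_c,
        )
    else:
        raise ValueError(f"unknown correction_scope {correction_scope!r}")
    return SubjectResult(
        accuracy=res["accuracy"],
        chosen_c=res["chosen_c"],
        n_train_per_class=res["n_train_per_class"],
        n_test_per_class=res["n_test_per_class"],
        fold_accuracies=res["fold_accuracies"],
        c_grid=tuple(spec.c_grid),
        target_condition=spec.target_condition,
        correction=None if correction == "none" else correction,
    )


def _decode_train_scope(
    V, sub, idx, y, runs, rng, spec, correction, *,
    standardize, loss, tune, fixed_c,
):
    """Variant estimating the projection from training trials only.

    The balanced set and split are drawn first (on uncorrected data — the
    projectors do not depend on class labels, so composition is unaffected),
    the projector is fit on the training rows, then applied to both rows.
    """
    from .projection import MeanSignalProjector, ResponseTimeResidualizer

    X = V[:, idx].T
    keep = downsample_balance(y, rng)
    Xb, yb, rb = X[keep], y[keep], runs[keep]
    rtb = sub["response_time_ms"].to_numpy(dtype=float)[keep]
    tr, te = split_train_test(yb, spec.train_fraction, rng)
    if correction == "mean_signal":
        proj = MeanSignalProjector().fit(Xb[tr])
        Xb = proj.transform(Xb)
    elif correction == "response_time":
        proj = ResponseTimeResidualizer().fit(Xb[tr], rt=rtb[tr])
        Xb = proj.transform(Xb, rt=rtb)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    svm_seed = int(rng.integers(2**31 - 1))
    if tune == "cv":
        chosen_c, fold_acc = tune_c(
            Xb[tr], yb[tr], rb[tr], c_grid=spec.c_grid, n_folds=spec.n_folds,
            standardize=standardize, loss=loss, seed=svm_seed,
        )
    else:
        chosen_c, fold_acc = float(fixed_c), None
    Xtr, Xte = Xb[tr], Xb[te]
    if standardize:
        mu, sd = _standardize_params(Xtr)
        Xtr, Xte = (Xtr - mu) / sd, (Xte - mu) / sd
    clf = _fit_svm(Xtr, yb[tr], chosen_c, loss, svm_seed)
    return {
        "accuracy": float(np.mean(clf.predict(Xte) == yb[te])),
        "chosen_c": chosen_c,
        "fold_accuracies": fold_acc,
        "n_train_per_class": int(yb[tr].sum()),
        "n_test_per_class": int(yb[te].sum()),
    }
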