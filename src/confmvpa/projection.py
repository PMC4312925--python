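"""Projection-based confound corrections for voxel-by-trial matrices.

Two corrections are provided for the voxel-by-trial amplitude matrix ``D``
(rows voxels, columns trials), each an orthogonal projection ``D' = D - PD``
applied before classifier training:

*Mean-signal removal* — each trial's pattern loses its component along the
unit-normalized voxel-wise mean response ``m̂``::

    D' = D - m̂ m̂ᵀ D

After correction every trial column is orthogonal to the region's mean
spatial pattern, so any decoding that survives cannot be driven by uniform
amplitude differences between conditions.

*Response-time residualization* — each voxel's across-trial response is
residualized on the mean-centered response-time vector ``r̃`` (the
residual-maker / annihilator projector acting on the trial dimension)::

    D' = D - D r̃ (r̃ᵀ r̃)⁻¹ r̃ᵀ

After correction no voxel covaries with response time, removing signal that
merely tracks task difficulty. ``mode="literal"`` instead applies the
identity-minus-annihilator form verbatim (retaining only the RT-spanned
component); it exists for comparison with that published formula, not for
analysis.

Both operators are exposed as scikit-learn transformers operating on
``(n_trials, n_voxels)`` arrays, with thin :func:`mean_correct` /
:func:`rt_correct` wrappers using the domain voxel-by-trial orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import PatternMatrix, as_matrix
from .exceptions import AlignmentError, DataError

__all__ = [
    "MeanSignalProjector",
    "ResponseTimeResidualizer",
    "CorrectedMatrix",
    "mean_correct",
    "rt_correct",
    "apply_correction",
    "CORRECTION_KINDS",
]

CORRECTION_KINDS = ("mean_signal", "response_time")

_DEGENERATE_NORM = 1e-12


class MeanSignalProjector(TransformerMixin, BaseEstimator):
    """Remove each trial's component along the voxel-wise mean pattern.

    ``fit`` estimates the region's mean spatial pattern from ``X`` (shape
    ``(n_trials, n_voxels)``); ``transform`` projects every row onto the
    orthogonal complement of that pattern. Fitting and transforming the same
    matrix reproduces ``D' = D - m̂ m̂ᵀ D``. If the mean pattern has
    negligible norm there is nothing to remove and the transform is the
    identity (with a warning).
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        m = X.mean(axis=0)
        norm = float(np.linalg.norm(m))
        self.n_features_in_ = X.shape[1]
        self.degenerate_ = norm < _DEGENERATE_NORM
        if self.degenerate_:
            warnings.warn(
                "voxel-wise mean pattern has ~zero norm; mean correction is "
                "the identity", stacklevel=2,
            )
            self.unit_mean_ = np.zeros_like(m)
        else:
            self.unit_mean_ = m / norm
        self.mean_norm_ = norm
        return self

    def transform(self, X):
        check_is_fitted(self, "unit_mean_")
        X = check_array(X, dtype=float)
        if self.degenerate_:
            return X.copy()
        u = self.unit_mean_
        return X - np.outer(X @ u, u)


class ResponseTimeResidualizer(TransformerMixin, BaseEstimator):
    """Residualize each voxel's across-trial response on response time.

    Parameters
    ----------
    mode
        ``"residualize"`` (default): remove the component of each voxel's
        trial series explained by mean-centered RT, preserving voxel means.
        ``"literal"``: apply ``D' = D - PD`` with
        ``P = I - r (rᵀ r)⁻¹ rᵀ`` on raw RT verbatim, which *keeps* only the
        RT-spanned component; provided for comparison only.

    ``fit`` expects ``X`` of shape ``(n_trials, n_voxels)`` and the aligned
    ``rt`` vector (ms). With constant RT there is nothing to remove and the
    transform is the identity (with a warning).
    """

    def __init__(self, mode: str = "residualize"):
        self.mode = mode

    def fit(self, X, y=None, *, rt=None):
        if self.mode not in ("residualize", "literal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        X = check_array(X, dtype=float)
        if rt is None:
            raise ValueError("rt (per-trial response times) is required")
        rt = np.asarray(rt, dtype=float).ravel()
        if len(rt) != X.shape[0]:
            raise AlignmentError(
                f"rt has {len(rt)} entries for {X.shape[0]} trials"
            )
        self.n_features_in_ = X.shape[1]
        self.rt_ = rt
        centered = rt - rt.mean()
        ss = float(centered @ centered)
        self.degenerate_ = ss < _DEGENERATE_NORM
        if self.degenerate_ and self.mode == "residualize":
            warnings.warn(
                "response times have zero variance; RT correction is the "
                "identity", stacklevel=2,
            )
        self.rt_centered_ = centered
        self.rt_ss_ = ss
        # per-voxel OLS slope of amplitude on centered RT
        self.slopes_ = (centered @ X) / ss if not self.degenerate_ else np.zeros(X.shape[1])
        return self

    def transform(self, X, rt=None):
        check_is_fitted(self, "rt_")
        X = check_array(X, dtype=float)
        if rt is None:
            rt = self.rt_
        rt = np.asarray(rt, dtype=float).ravel()
        if len(rt) != X.shape[0]:
            raise AlignmentError("rt misaligned with X rows")
        if self.mode == "literal":
            r = rt
            ss = float(r @ r)
            if ss < _DEGENERATE_NORM:
                return np.zeros_like(X)
            return np.outer(r, (r @ X) / ss)
        if self.degenerate_:
            return X.copy()
        centered = rt - self.rt_.mean()
        return X - np.outer(centered, self.slopes_)

    def fit_transform(self, X, y=None, *, rt=None):
        return self.fit(X, rt=rt).transform(X)


@dataclass
class CorrectedMatrix:
    """A corrected voxel-by-trial matrix plus orthogonality diagnostics."""

    values: np.ndarray
    correction: str | None
    diagnostics: dict = field(default_factory=dict)

    @property
    def matrix(self) -> PatternMatrix:
        return PatternMatrix(self.values)


def mean_correct(D: PatternMatrix | np.ndarray) -> CorrectedMatrix:
    """Mean-signal projection of a voxel-by-trial matrix.

    Diagnostics record the worst column-wise residual alignment with the
    unit mean pattern, relative to that column's norm (contract: <= 1e-8).
    """
    V = as_matrix(D)
    if V.shape[1] < 2:
        raise DataError("mean correction needs at least 2 trials")
    proj = MeanSignalProjector().fit(V.T)
    out = proj.transform(V.T).T
    u = proj.unit_mean_
    col_norms = np.linalg.norm(out, axis=0)
    resid = np.abs(u @ out)
    rel = np.where(col_norms > 0, resid / np.maximum(col_norms, _DEGENERATE_NORM), 0.0)
    diags = {
        "max_rel_mean_alignment": float(rel.max()) if rel.size else 0.0,
        "mean_pattern_norm": proj.mean_norm_,
        "degenerate": bool(proj.degenerate_),
    }
    return CorrectedMatrix(out, "mean_signal", diags)


def rt_correct(
    D: PatternMatrix | np.ndarray,
    trials: pd.DataFrame | np.ndarray,
    mode: str = "residualize",
) -> CorrectedMatrix:
    """Response-time residualization of a voxel-by-trial matrix.

    ``trials`` is either a trial table (``response_time_ms`` column) or a
    bare RT vector aligned to D's columns. Diagnostics record the worst
    per-voxel covariance of the output with RT, relative to the input row
    norms (contract: <= 1e-8 for the residualizing mode).
    """
    V = as_matrix(D)
    rt = (
        np.asarray(trials["response_time_ms"], dtype=float)
        if isinstance(trials, pd.DataFrame)
        else np.asarray(trials, dtype=float).ravel()
    )
    if len(rt) != V.shape[1]:
        raise AlignmentError(
            f"{len(rt)} response times for {V.shape[1]} trial columns"
        )
    if V.shape[1] < 3:
        raise DataError("RT correction needs at least 3 trials")
    res = ResponseTimeResidualizer(mode=mode).fit(V.T, rt=rt)
    out = res.transform(V.T).T
    centered = rt - rt.mean()
    cov = np.abs(out @ centered)
    scale = np.linalg.norm(V, axis=1) * np.linalg.norm(centered)
    rel = np.where(scale > 0, cov / np.maximum(scale, _DEGENERATE_NORM), 0.0)
    diags = {
        "max_rel_rt_covariance": float(rel.max()) if rel.size else 0.0,
        "degenerate": bool(res.degenerate_),
        "mode": mode,
    }
    return CorrectedMatrix(out, "response_time", diags)


def apply_correction(
    D: PatternMatrix | np.ndarray,
    trials: pd.DataFrame | None,
    kind: str | None,
) -> CorrectedMatrix:
    """Dispatch to the requested correction; ``kind=None`` is the identity."""
    if kind in (None, "none"):
        return CorrectedMatrix(as_matrix(D).copy(), None, {})
    if kind == "mean_signal":
        return mean_correct(D)
    if kind == "response_time":
        if trials is None:
            raise DataError("response_time correction requires a trial table")
        return rt_correct(D, trials)
    raise ValueError(
        f"unknown correction kind {kind!r}; expected one of "
        f"{('none',) + CORRECTION_KINDS}"
    )
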