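"""Core data containers: trial tables and voxel-by-trial pattern matrices.

A *trial table* is a :class:`pandas.DataFrame` with one row per retrieval
trial and columns ``trial_id``, ``condition``, ``response_time_ms``,
``run_id``, ``correct`` and (when event timing is simulated) ``onset_s``.
A *pattern matrix* holds the voxel-by-trial matrix of single-trial response
amplitudes, ``D``: rows are voxels of one region of interest, columns are
trials, and column ``j`` is aligned with row ``j`` of the trial table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError

#: The three retrieval conditions, in canonical order.
CONDITIONS: tuple[str, ...] = ("spatial", "temporal", "pair")

TRIAL_COLUMNS = ("trial_id", "condition", "response_time_ms", "run_id", "correct")


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table invariants and return the table unchanged.

    Raises
    ------
    ConfigurationError
        If a required column is missing, a condition label is unknown, or a
        response time is not strictly positive.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ConfigurationError(f"trial table is missing columns: {missing}")
    bad = set(trials["condition"]) - set(CONDITIONS)
    if bad:
        raise ConfigurationError(f"unknown condition labels: {sorted(bad)}")
    rt = np.asarray(trials["response_time_ms"], dtype=float)
    if not np.all(rt > 0):
        raise ConfigurationError("response_time_ms must be > 0 for every trial")
    if "onset_s" in trials.columns:
        for run_id, run in trials.groupby("run_id"):
            onsets = np.asarray(run["onset_s"], dtype=float)
            if np.any(onsets < 0) or np.any(np.diff(onsets) <= 0):
                raise ConfigurationError(
                    f"onsets in run {run_id} must be nonnegative, strictly increasing"
                )
    return trials


@dataclass
class PatternMatrix:
    """Voxel-by-trial matrix of response amplitudes for one subject/ROI.

    Parameters
    ----------
    values
        Array of shape ``(n_voxels, n_trials)``; entries must be finite.
    voxel_ids
        Ordered voxel labels; generated as ``v0000 ...`` when omitted.
    """

    values: np.ndarray
    voxel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise AlignmentError("pattern matrix must be 2-D (voxels x trials)")
        if not np.all(np.isfinite(self.values)):
            raise AlignmentError("pattern matrix contains non-finite entries")
        if not self.voxel_ids:
            self.voxel_ids = [f"v{i:04d}" for i in range(self.values.shape[0])]
        elif len(self.voxel_ids) != self.values.shape[0]:
            raise AlignmentError(
                f"{len(self.voxel_ids)} voxel_ids for {self.values.shape[0]} voxel rows"
            )

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def check_aligned(self, trials: pd.DataFrame) -> None:
        """Raise :class:`AlignmentError` unless columns match trial rows."""
        if self.n_trials != len(trials):
            raise AlignmentError(
                f"matrix has {self.n_trials} trial columns but the trial table "
                f"has {len(trials)} rows"
            )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=pd.Index(self.voxel_ids, name="voxel_id"))
        df.columns = [f"trial{j:04d}" for j in range(self.n_trials)]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PatternMatrix":
        return cls(values=df.to_numpy(dtype=float), voxel_ids=[str(v) for v in df.index])


def as_matrix(D: "PatternMatrix | np.ndarray") -> np.ndarray:
    """Return the underlying voxel-by-trial ndarray of ``D``."""
    if isinstance(D, PatternMatrix):
        return D.values
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2:
        raise AlignmentError("expected a 2-D voxel-by-trial array")
    return arr
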