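"""File interfaces: TSV trial tables and matrices, YAML configs, NIfTI.

Trial tables travel as headered TSV; pattern matrices as TSV with a
``voxel_id`` first column (voxels in rows, trials in columns). Real data can
enter as a 4-D NIfTI beta series (one volume per trial) with a 3-D mask,
via nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ClassifierSpec, SimulationConfig
from .data import PatternMatrix, validate_trial_table
from .exceptions import AlignmentError, ConfigurationError


def write_trial_table(trials: pd.DataFrame, path) -> None:
    validate_trial_table(trials).to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return validate_trial_table(pd.read_csv(path, sep="\t"))


def write_matrix(D: PatternMatrix, path) -> None:
    D.to_dataframe().to_csv(path, sep="\t")


def read_matrix(path) -> PatternMatrix:
    df = pd.read_csv(path, sep="\t", index_col="voxel_id")
    return PatternMatrix.from_dataframe(df)


def load_simulation_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML mapping."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    try:
        return SimulationConfig(**payload)
    except TypeError as err:
        raise ConfigurationError(f"{path}: {err}") from err


def load_classifier_spec(path) -> ClassifierSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    try:
        return ClassifierSpec(**payload)
    except TypeError as err:
        raise ConfigurationError(f"{path}: {err}") from err


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_beta_series(beta_path, mask_path) -> tuple[PatternMatrix, np.ndarray]:
    """Voxel-by-trial matrix from a 4-D NIfTI beta series and 3-D mask.

    Returns the matrix (rows ordered by flat index of in-mask voxels) and
    the boolean mask array, so estimates can be written back to volumes.
    """
    import nibabel as nib

    img = nib.load(str(beta_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise AlignmentError("beta series must be 4-D (x, y, z, trial)")
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise AlignmentError("mask shape does not match beta volumes")
    flat = np.flatnonzero(mask.ravel())
    values = data.reshape(-1, data.shape[3])[flat]
    voxel_ids = [f"vox{i}" for i in flat]
    return PatternMatrix(values, voxel_ids), mask


def save_beta_series(D: PatternMatrix, mask: np.ndarray, path, affine=None) -> None:
    """Write a voxel-by-trial matrix back into a 4-D NIfTI beta series."""
    import nibabel as nib

    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) != D.n_voxels:
        raise AlignmentError("mask voxel count does not match matrix rows")
    vol = np.zeros(mask.shape + (D.n_trials,))
    vol[mask] = D.values
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(vol, affine), str(path))
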