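"""Configuration objects for simulation and classification.

:class:`SimulationConfig` describes one synthetic multi-subject experiment:
the trial design (three retrieval conditions crossed over runs), the
per-condition response-time distributions, and three orthogonal ground-truth
signal components that can be injected into the voxel-by-trial amplitude
matrix:

``pattern_effect``
    magnitude of condition-specific *distributed* patterns (zero-mean,
    unit-norm across voxels, so they leave the spatial mean untouched);
``mean_effect``
    per-condition uniform amplitude offsets (a pure spatial-mean signal);
``rt_coupling``
    a spatially uniform gain on the trial's response-time deviation, so that
    amplitude covaries with behavior (a task-difficulty proxy) rather than
    with condition per se.

A config with all three at zero is the null scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

from .data import CONDITIONS
from .exceptions import ConfigurationError

#: Mean response times (ms) for correct spatial / temporal / pair trials,
#: matching the observed behavioral means of the retrieval task.
DEFAULT_RT_MEAN_MS: dict[str, float] = {
    "spatial": 1284.0,
    "temporal": 1384.0,
    "pair": 1183.0,
}

#: Within-subject trial-to-trial RT standard deviation (ms). The source data
#: report only across-subject SEs; 200 ms is a typical single-trial spread
#: for speeded recognition responses.
DEFAULT_RT_SD_MS = 200.0

#: Lower truncation bound (ms) for simulated response times.
RT_TRUNCATION_MS = 200.0


def _per_condition(value, default: float, name: str) -> dict[str, float]:
    """Broadcast a scalar or fill a partial mapping to all conditions."""
    if value is None:
        return {c: default for c in CONDITIONS}
    if isinstance(value, Mapping):
        bad = set(value) - set(CONDITIONS)
        if bad:
            raise ConfigurationError(f"{name}: unknown conditions {sorted(bad)}")
        return {c: float(value.get(c, default)) for c in CONDITIONS}
    return {c: float(value) for c in CONDITIONS}


@dataclass
class SimulationConfig:
    """Ground-truth generative settings for one synthetic experiment."""

    n_subjects: int = 17
    n_voxels: int = 40
    trials_per_condition: int = 80
    n_runs: int = 5
    baseline: float = 1.0
    pattern_effect: float = 0.0
    #: scalar -> offset applied to the *pair* condition only (the direction
    #: of the observed univariate effect); mapping -> explicit per-condition.
    mean_effect: float | Mapping[str, float] | None = None
    rt_mean_ms: Mapping[str, float] | None = None
    rt_sd_ms: float | Mapping[str, float] = DEFAULT_RT_SD_MS
    rt_coupling: float = 0.0
    noise_sd: float = 1.0
    incorrect_rate: float = 0.16
    run_duration_s: float = 387.5
    trial_duration_s: float = 4.0
    min_jitter_s: float = 0.5
    max_jitter_s: float = 13.0
    seed: int = 0

    mean_offsets: dict[str, float] = field(init=False)
    rt_means: dict[str, float] = field(init=False)
    rt_sds: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_voxels", "trials_per_condition", "n_runs"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.incorrect_rate < 1.0:
            raise ConfigurationError("incorrect_rate must be in [0, 1)")
        if self.min_jitter_s <= 0 or self.max_jitter_s <= self.min_jitter_s:
            raise ConfigurationError("jitter bounds must satisfy 0 < min < max")

        if self.mean_effect is None:
            self.mean_offsets = {c: 0.0 for c in CONDITIONS}
        elif isinstance(self.mean_effect, Mapping):
            self.mean_offsets = _per_condition(self.mean_effect, 0.0, "mean_effect")
        else:
            self.mean_offsets = {c: 0.0 for c in CONDITIONS}
            self.mean_offsets["pair"] = float(self.mean_effect)

        self.rt_means = _per_condition(
            self.rt_mean_ms, 0.0, "rt_mean_ms"
        ) if self.rt_mean_ms is not None else dict(DEFAULT_RT_MEAN_MS)
        self.rt_sds = _per_condition(self.rt_sd_ms, DEFAULT_RT_SD_MS, "rt_sd_ms")
        for c in CONDITIONS:
            if self.rt_sds[c] <= 0:
                raise ConfigurationError("rt_sd_ms must be > 0")
            if self.rt_means[c] <= RT_TRUNCATION_MS:
                raise ConfigurationError(
                    f"rt_mean_ms for {c} must exceed the {RT_TRUNCATION_MS:.0f} ms "
                    "truncation bound"
                )

    @property
    def is_null(self) -> bool:
        """True when no condition-linked signal component is injected."""
        return (
            self.pattern_effect == 0.0
            and all(v == 0.0 for v in self.mean_offsets.values())
            and self.rt_coupling == 0.0
        )

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            if not f.init:
                continue
            v = getattr(self, f.name)
            out[f.name] = dict(v) if isinstance(v, Mapping) else v
        return out


#: Default regularization grid: 11 decade steps spanning 1e-10 ... 1.
DEFAULT_C_GRID: tuple[float, ...] = tuple(10.0 ** k for k in range(-10, 1))


@dataclass
class ClassifierSpec:
    """Settings of the per-subject binary decoding scheme."""

    target_condition: str = "pair"
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_condition not in CONDITIONS:
            raise ConfigurationError(
                f"target_condition must be one of {CONDITIONS}"
            )
        grid = tuple(float(c) for c in self.c_grid)
        if len(grid) == 0 or any(c <= 0 for c in grid):
            raise ConfigurationError("c_grid must contain positive values")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigurationError("c_grid must be strictly increasing")
        self.c_grid = grid
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
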