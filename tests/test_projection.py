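"""Projection operators: orthogonality contracts, oracles, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from confmvpa import (
    AlignmentError,
    DataError,
    MeanSignalProjector,
    ResponseTimeResidualizer,
    SimulationConfig,
    apply_correction,
    mean_correct,
    rt_correct,
    simulate_subject,
)

TOL = 1e-8


def _rel(x, ref):
    return np.abs(x) / max(np.linalg.norm(ref), 1e-300)


class TestMeanCorrect:
    def test_columns_orthogonal_to_mean_pattern_and_idempotent(self, rng):
        D = rng.normal(1.0, 1.0, size=(50, 120))
        out = mean_correct(D)
        m = D.mean(axis=1)
        u = m / np.linalg.norm(m)
        col_norms = np.linalg.norm(out.values, axis=0)
        assert np.all(np.abs(u @ out.values) <= TOL * np.maximum(col_norms, 1e-300))
        assert out.diagnostics["max_rel_mean_alignment"] <= TOL
        twice = mean_correct(out.values)
        assert np.allclose(twice.values, out.values, atol=TOL)

    def test_columns_in_mean_span_are_annihilated(self, rng):
        m = rng.normal(size=30)
        scales = rng.normal(size=40) + 5.0  # keep voxel means aligned with m
        D = np.outer(m, scales)
        out = mean_correct(D)
        assert np.allclose(out.values, 0.0, atol=1e-10 * np.linalg.norm(D))

    def test_zero_mean_matrix_returned_unchanged(self, rng):
        D = rng.normal(size=(20, 40))
        D -= D.mean(axis=1, keepdims=True)  # voxel means exactly 0
        with pytest.warns(UserWarning, match="zero norm|identity"):
            out = mean_correct(D)
        assert np.array_equal(out.values, D)
        assert out.diagnostics["degenerate"]

    def test_requires_two_trials(self):
        with pytest.raises(DataError):
            mean_correct(np.ones((5, 1)))


class TestRtCorrect:
    def test_matches_per_voxel_regression_residuals(self, rng):
        # independent oracle: per-voxel OLS (intercept + RT) residuals plus
        # the voxel mean, via numpy polyfit
        D = rng.normal(size=(30, 80))
        rt = rng.uniform(600, 2500, size=80)
        out = rt_correct(D, rt)
        for v in range(30):
            slope, intercept = np.polyfit(rt, D[v], 1)
            resid = D[v] - (slope * rt + intercept)
            expected = resid + D[v].mean()
            assert np.allclose(out.values[v], expected, atol=1e-8)

    def test_idempotent_and_rt_decorrelated(self, rng):
        D = rng.normal(size=(15, 60))
        rt = rng.uniform(500, 3000, size=60)
        out = rt_correct(D, rt)
        centered = rt - rt.mean()
        assert np.all(_rel(out.values @ centered, D) <= TOL * np.linalg.norm(centered))
        assert out.diagnostics["max_rel_rt_covariance"] <= TOL
        twice = rt_correct(out.values, rt)
        assert np.allclose(twice.values, out.values, atol=TOL)

    def test_pure_rt_signal_reduced_to_voxel_means(self, rng):
        # D[v,t] = w[v] * centered_rt[t] has no mean and no residual
        rt = rng.uniform(800, 2000, size=50)
        w = rng.normal(size=10)
        D = np.outer(w, rt - rt.mean())
        out = rt_correct(D, rt)
        assert np.allclose(out.values, 0.0, atol=1e-8)

    def test_equal_rts_identity_with_warning(self, rng):
        D = rng.normal(size=(8, 20))
        with pytest.warns(UserWarning, match="zero variance"):
            out = rt_correct(D, np.full(20, 1200.0))
        assert np.array_equal(out.values, D)

    def test_voxel_means_preserved(self, rng):
        D = rng.normal(3.0, 1.0, size=(12, 40))
        rt = rng.uniform(600, 2200, size=40)
        out = rt_correct(D, rt)
        assert np.allclose(out.values.mean(axis=1), D.mean(axis=1), atol=1e-10)

    def test_additive_model_recovers_intercept_plus_noise(self, rng):
        # D = a[v] + w[v]*centered_rt + noise -> output slope on RT is 0
        rt = rng.uniform(700, 2100, size=100)
        c = rt - rt.mean()
        a = rng.normal(size=6)
        w = rng.normal(size=6)
        noise = 0.01 * rng.normal(size=(6, 100))
        D = a[:, None] + np.outer(w, c) + noise
        out = rt_correct(D, rt)
        for v in range(6):
            slope = np.polyfit(rt, out.values[v], 1)[0]
            assert abs(slope) < 1e-8

    def test_misalignment_raises(self, rng):
        with pytest.raises(AlignmentError):
            rt_correct(rng.normal(size=(4, 10)), np.ones(7))

    def test_literal_mode_keeps_only_rt_span(self, rng):
        # the verbatim identity-minus-annihilator form retains the component
        # spanned by raw RT: D' = r (r'r)^-1 r' D (trial dimension)
        D = rng.normal(size=(9, 25))
        rt = rng.uniform(500, 2500, size=25)
        out = rt_correct(D, rt, mode="literal")
        P = np.eye(25) - np.outer(rt, rt) / (rt @ rt)
        expected = D - D @ P
        assert np.allclose(out.values, expected, atol=1e-8)


class TestTransformers:
    def test_sklearn_params_roundtrip(self):
        res = ResponseTimeResidualizer(mode="literal")
        assert res.get_params() == {"mode": "literal"}
        res.set_params(mode="residualize")
        assert res.mode == "residualize"

    def test_projector_train_then_transform_new_data(self, rng):
        Xtr = rng.normal(1.0, 1.0, size=(40, 10))
        Xte = rng.normal(1.0, 1.0, size=(8, 10))
        proj = MeanSignalProjector().fit(Xtr)
        out = proj.transform(Xte)
        assert np.all(np.abs(out @ proj.unit_mean_) <= 1e-8 *
                      np.linalg.norm(Xte, axis=1))


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    D=arrays(np.float64, (6, 18), elements=st.floats(-10, 10)),
    a=st.floats(-3, 3),
    b=st.floats(-3, 3),
)
def test_rt_residualizer_is_linear_at_fixed_rt(D, a, b):
    rt = np.linspace(500, 2500, 18)
    D2 = np.cos(D) + 0.5
    lhs = rt_correct(a * D + b * D2, rt).values
    rhs = a * rt_correct(D, rt).values + b * rt_correct(D2, rt).values
    assert np.allclose(lhs, rhs, atol=1e-7)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(D=arrays(np.float64, (7, 15), elements=st.floats(-50, 50)))
def test_projections_never_increase_frobenius_norm(D):
    rt = np.linspace(400, 2600, 15)
    norm = np.linalg.norm(D)
    assert np.linalg.norm(mean_correct(D).values) <= norm + 1e-9
    assert np.linalg.norm(rt_correct(D, rt).values) <= norm + 1e-9


class TestApplyCorrection:
    def test_none_is_identity(self, null_subject):
        trials, D, _ = null_subject
        out = apply_correction(D, trials, None)
        assert np.array_equal(out.values, D.values)
        assert out.correction is None

    def test_unknown_kind_raises(self, null_subject):
        trials, D, _ = null_subject
        with pytest.raises(ValueError, match="unknown correction"):
            apply_correction(D, trials, "motion")

    def test_mean_correction_collapses_pure_mean_centroids(self):
        cfg = SimulationConfig(mean_effect={"pair": 2.0}, noise_sd=0.01,
                               n_voxels=25, trials_per_condition=200, n_runs=1)
        trials, D, _ = simulate_subject(cfg, 4)
        cond = trials["condition"].to_numpy()
        raw_cents = {c: D.values[:, cond == c].mean(axis=1)
                     for c in ("pair", "spatial")}
        assert np.linalg.norm(raw_cents["pair"] - raw_cents["spatial"]) > 1.0
        out = apply_correction(D, trials, "mean_signal")
        cents = {c: out.values[:, cond == c].mean(axis=1)
                 for c in ("pair", "spatial")}
        assert np.linalg.norm(cents["pair"] - cents["spatial"]) < 0.05

    def test_rt_correction_removes_rt_coupling(self):
        cfg = SimulationConfig(rt_coupling=0.01, noise_sd=0.01,
                               n_voxels=15, trials_per_condition=200, n_runs=1)
        trials, D, _ = simulate_subject(cfg, 6)
        rt = trials["response_time_ms"].to_numpy()
        out = apply_correction(D, trials, "response_time")
        for v in range(15):
            r = np.corrcoef(out.values[v], rt)[0, 1]
            assert abs(r) < 0.05
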