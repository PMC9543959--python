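"""Synthetic generator structure, schedules, adaptation and ballistic utilities."""

import numpy as np
import pytest

from taskmodules import (
    PerformanceSeries,
    SyntheticConfig,
    chain_endpoint_height,
    cross_validate,
    detect_release,
    fit_relevance_map,
    fourier_basis,
    generate_motion,
    generate_performance,
    module_fragments,
    decompose_relevance,
    parabola_height,
    perturbation_correlation,
    perturbation_schedule,
    planted_relevance_map,
    simulate_adaptation,
    standardize_per_joint,
)


def test_fourier_basis_is_orthonormal_with_flat_energy():
    B = fourier_basis(60, 11)
    np.testing.assert_allclose(B.T @ B, np.eye(11), atol=1e-12)
    np.testing.assert_allclose((B**2).sum(axis=1), 11 / 60, atol=1e-12)


def test_noiseless_rank_one_trials_are_rank_one():
    cfg = SyntheticConfig(I=4, J=20, K=5, rank_motion=1, noise_sd_motion=0.0, seed=0)
    ds = generate_motion(cfg)
    for k in range(5):
        sv = np.linalg.svd(ds.angles[:, :, k], compute_uv=False)
        assert sv[1] < 1e-10 * sv[0]


def test_seed_reproducibility_bit_identical():
    cfg = SyntheticConfig(K=12, seed=77)
    a = generate_motion(cfg).angles
    b = generate_motion(SyntheticConfig(K=12, seed=77)).angles
    assert np.array_equal(a, b)
    d1, p1 = simulate_adaptation(SyntheticConfig(K=40, seed=5))
    d2, p2 = simulate_adaptation(SyntheticConfig(K=40, seed=5))
    assert np.array_equal(d1.angles, d2.angles)
    assert np.array_equal(p1.d_raw, p2.d_raw)


def test_singular_value_profile_shows_planted_rank():
    """At SNR 10 the planted modules dominate the spatial spectrum."""
    cfg = SyntheticConfig(K=100, rank_motion=2, seed=1)
    ds = generate_motion(cfg)
    sv = np.linalg.svd(ds.angles.reshape(4, -1), compute_uv=False)
    assert sv[1] / sv[2] > 5.0  # two dominant modes, then the noise floor


def test_iid_null_mode_has_flat_spectrum():
    cfg = SyntheticConfig(K=100, rank_motion=0, seed=2)
    ds = generate_motion(cfg)
    sv = np.linalg.svd(ds.angles.reshape(4, -1), compute_uv=False)
    assert sv[0] / sv[-1] < 1.3


class TestGeneratePerformance:
    def test_noiseless_map_is_perfectly_predictable(self):
        cfg = SyntheticConfig(K=120, seed=3)
        ds = generate_motion(cfg)
        W, _, _, _ = planted_relevance_map(4, 60, 2, seed=4)
        perf, signal = generate_performance(ds, W, 0.0, seed=5)
        np.testing.assert_array_equal(perf.d_raw, signal)
        _, cv, _ = cross_validate(ds, perf, [1e-6], seed=0)
        assert cv < 0.02

    def test_zero_map_gives_unpredictable_performance(self):
        cfg = SyntheticConfig(K=120, seed=6)
        ds = generate_motion(cfg)
        perf, signal = generate_performance(ds, np.zeros((4, 60)), 1.0, seed=7)
        assert not signal.any()
        _, cv, _ = cross_validate(ds, perf, seed=0)
        assert 0.8 < cv < 1.25

    def test_recovered_map_correlates_with_planted(self):
        cfg = SyntheticConfig(K=200, seed=8)
        ds = generate_motion(cfg)
        W, _, _, _ = planted_relevance_map(4, 60, 2, seed=9)
        sig = np.einsum("ij,ijk->k", W, standardize_per_joint(ds).X)
        perf, _ = generate_performance(ds, W, 0.1 * sig.std(), seed=10)
        model = fit_relevance_map(ds, perf, seed=0)
        r = np.corrcoef(model.W.ravel(), W.ravel())[0, 1]
        assert r > 0.9

    def test_shape_mismatch(self):
        ds = generate_motion(SyntheticConfig(K=10, seed=0))
        with pytest.raises(ValueError, match="shape"):
            generate_performance(ds, np.zeros((3, 60)), 0.1)


class TestPerturbationSchedule:
    def test_printed_ramp_value_at_trial_twenty(self):
        """Baseline 10, ramp 10 at 0.005/trial puts exactly 0.05 at trial 20."""
        cfg = SyntheticConfig(K=30, seed=0)
        p = perturbation_schedule(cfg)
        assert p[19] == 0.05  # 20th trial, 1-based
        assert p[19] == 10 * 0.005

    def test_matches_piecewise_closed_form(self):
        cfg = SyntheticConfig(
            K=40, baseline_trials=7, ramp_trials=12, ramp_step=0.01, seed=0
        )
        p = perturbation_schedule(cfg)
        for k in range(40):
            if k < 7:
                assert p[k] == 0.0
            elif k < 19:
                assert p[k] == pytest.approx((k - 7 + 1) * 0.01)
            else:
                assert p[k] == pytest.approx(0.12)

    def test_zero_step_is_all_zero(self):
        cfg = SyntheticConfig(K=25, ramp_step=0.0, hold_value=0.0, seed=0)
        assert not perturbation_schedule(cfg).any()

    def test_infeasible_lengths(self):
        with pytest.raises(ValueError, match="exceeds"):
            perturbation_schedule(SyntheticConfig(K=15, seed=0))


class TestSimulateAdaptation:
    def _fragment_correlations(self, cfg):
        ds, perf = simulate_adaptation(cfg)
        model = fit_relevance_map(ds, perf, sigma2=1.0, seed=0)
        tm = decompose_relevance(model.W, rank=2)
        frag = module_fragments(tm, model.joint_std.X, model.const)
        return perturbation_correlation(frag, perf.perturbation)

    def test_zero_gain_no_correlation(self):
        rho = self._fragment_correlations(
            SyntheticConfig(K=60, adaptation_gain=0.0, seed=11)
        )
        assert abs(rho[0]) < 0.4

    def test_strong_gain_low_noise_strongly_negative(self):
        rho = self._fragment_correlations(
            SyntheticConfig(
                K=60, adaptation_gain=30.0, noise_sd_perf=0.01, seed=12
            )
        )
        assert rho[0] < -0.9

    def test_default_conditions_sign_is_negative(self):
        rho = self._fragment_correlations(SyntheticConfig(K=60, seed=13))
        assert rho[0] < -0.5


def test_parabola_height_values():
    assert parabola_height(0.0, 0.0) == 0.0
    assert parabola_height(0.3, 0.0) == 0.3
    assert parabola_height(0.1, 1.4) == pytest.approx(0.2)  # 0.1 + 1.96/19.6


class TestDetectRelease:
    def test_first_crossing_of_ten_percent(self):
        assert detect_release([0.0, 0.0, 0.05, 0.2, 1.0]) == 3

    def test_monotone_ramp(self):
        series = np.linspace(0, 1, 11)
        assert detect_release(series) == 2  # first value strictly above 0.1

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(20):
            peak = int(rng.integers(5, 45))
            series = np.concatenate(
                [np.linspace(0, 1, peak), np.linspace(1, 0.2, 50 - peak)]
            )
            series += 0.01 * rng.random(50)
            idx = detect_release(series)
            thresh = 0.1 * series.max()
            scan = next(i for i, v in enumerate(series) if v > thresh)
            assert idx == scan

    def test_flat_zero_series_errors(self):
        with pytest.raises(ValueError, match="ground"):
            detect_release(np.zeros(10))


def test_chain_endpoint_height():
    # two unit segments, both at 90 deg: height = 1 + sin(pi) = 1
    q = np.array([np.pi / 2, np.pi / 2])
    assert chain_endpoint_height(q, [1.0, 1.0]) == pytest.approx(1.0)
    # single segment at 30 deg
    assert chain_endpoint_height(np.array([np.pi / 6]), [2.0]) == pytest.approx(1.0)


def test_config_validation():
    with pytest.raises(ValueError, match="rank_motion"):
        SyntheticConfig(I=2, J=10, rank_motion=3)
    with pytest.raises(ValueError, match="noise"):
        SyntheticConfig(noise_sd_motion=-0.1)
    cfg = SyntheticConfig()
    assert cfg.hold_value == pytest.approx(cfg.ramp_step * cfg.ramp_trials)
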