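"""Composite quantile objective: closed forms, limits, invariants."""

import numpy as np
import pytest

from dp5q.autodiff import Tensor
from dp5q.losses import (
    LossConfig,
    QuantileGrid,
    huber,
    monotonicity_penalty,
    multi_quantile_loss,
    pinball,
    quantile_loss,
    total_loss,
)


class TestHuber:
    def test_zero_residual(self):
        assert huber(0.0) == 0.0

    def test_linear_branch_closed_form(self):
        # |r| - delta/2 for |r| > delta
        assert huber(0.5, 1e-4) == pytest.approx(0.49995, abs=1e-12)

    def test_quadratic_branch_closed_form(self):
        # r^2 / (2 delta) for |r| <= delta
        assert huber(5e-5, 1e-4) == pytest.approx(1.25e-5, rel=1e-12)

    def test_continuity_and_smoothness_at_transition(self):
        d = 1e-4
        eps = 1e-9
        assert huber(d - eps, d) == pytest.approx(huber(d + eps, d), abs=3 * eps)
        # first derivative continuous: slope ~1 on both sides of |r|=delta
        slope_in = (huber(d, d) - huber(d - 1e-8, d)) / 1e-8
        slope_out = (huber(d + 1e-8, d) - huber(d, d)) / 1e-8
        assert slope_in == pytest.approx(slope_out, abs=1e-3)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            huber(1.0, 0.0)


class TestQuantileLoss:
    def test_asymmetry_ratio_is_tau_over_one_minus_tau(self):
        # tau = 0.75: under-prediction costs 3x over-prediction (delta -> 0)
        under = quantile_loss(y=1.0, yhat=0.0, tau=0.75)
        over = quantile_loss(y=0.0, yhat=1.0, tau=0.75)
        assert under / over == pytest.approx(3.0, rel=1e-3)

    def test_symmetric_at_median(self):
        under = quantile_loss(y=1.0, yhat=0.0, tau=0.5)
        over = quantile_loss(y=0.0, yhat=1.0, tau=0.5)
        assert under == pytest.approx(over, rel=1e-12)

    def test_exact_prediction_has_no_loss(self):
        assert quantile_loss(y=42.0, yhat=42.0, tau=0.3) == 0.0

    def test_tau_out_of_range_fatal(self):
        for tau in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                quantile_loss(1.0, 0.0, tau)

    def test_pinball_limit_bound_over_grid(self):
        # |quantile_loss(delta) - pinball| <= delta/2 for all residuals, all taus
        delta = 1e-4
        residuals = np.concatenate(
            [np.linspace(-100, 100, 2001), [-delta, 0.0, delta, delta / 2]]
        )
        taus = QuantileGrid().array
        for tau in taus:
            ql = quantile_loss(residuals, np.zeros_like(residuals), tau, delta)
            pb = pinball(residuals, np.zeros_like(residuals), tau)
            assert np.max(np.abs(ql - pb)) <= delta / 2 + 1e-15


class TestMultiQuantileLoss:
    def test_zero_iff_all_entries_equal_y(self):
        grid = QuantileGrid()
        cfg = LossConfig(grid=grid)
        y = 123.4
        assert multi_quantile_loss(y, np.full((1, 99), y), cfg)[0] == 0.0
        assert multi_quantile_loss(y, np.full((1, 99), y + 1), cfg)[0] > 0.0

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(0)
        grid = QuantileGrid()
        cfg = LossConfig(grid=grid)
        y = 50.0
        yhat = 50.0 + rng.normal(scale=5.0, size=99)
        total = multi_quantile_loss(y, yhat[None, :], cfg)[0]
        brute = sum(
            quantile_loss(y, yhat[k], tau, cfg.delta) for k, tau in enumerate(grid.taus)
        )
        assert total == pytest.approx(brute, rel=1e-12)

    def test_single_median_grid_reduces_to_half_mae(self):
        grid = QuantileGrid((0.5,))
        cfg = LossConfig(grid=grid, delta=1e-10)
        errs = np.array([1.0, -2.0, 3.5])
        vals = multi_quantile_loss(0.0, -errs[:, None], cfg)
        assert np.allclose(vals, 0.5 * np.abs(errs), atol=1e-9)

    def test_length_mismatch_fatal(self):
        with pytest.raises(ValueError):
            multi_quantile_loss(1.0, np.zeros((1, 5)), LossConfig())

    def test_scale_behaviour_in_linear_regime(self):
        rng = np.random.default_rng(1)
        cfg = LossConfig()
        resid = rng.normal(scale=10.0, size=(4, 99))  # residuals >> delta
        base = multi_quantile_loss(0.0, resid, cfg).sum()
        scaled = multi_quantile_loss(0.0, 3.0 * resid, cfg).sum()
        assert scaled / base == pytest.approx(3.0, rel=0.01)


class TestMonotonicityPenalty:
    def test_zero_on_strictly_increasing_with_margin(self):
        v = np.cumsum(np.full(99, 1e-3))
        assert monotonicity_penalty(v, epsilon=1e-6) == 0.0

    def test_hinge_closed_form_on_crossing_pair(self):
        assert monotonicity_penalty(np.array([5.0, 4.0]), 1e-6) == pytest.approx(
            1.000001, rel=1e-12
        )

    def test_constant_vector_contributes_epsilon_per_pair(self):
        v = np.full(99, 7.0)
        assert monotonicity_penalty(v, 1e-6) == pytest.approx(98e-6, rel=1e-9)

    def test_needs_two_entries(self):
        with pytest.raises(ValueError):
            monotonicity_penalty(np.array([1.0]))


class TestTotalLoss:
    def test_reduces_to_quantile_term_when_weight_zero(self):
        rng = np.random.default_rng(2)
        cfg = LossConfig(mono_weight=0.0)
        y = rng.normal(size=3) * 10 + 100
        yhat = y[:, None] + rng.normal(size=(3, 99))
        assert total_loss(y, yhat, cfg) == pytest.approx(
            float(np.mean(multi_quantile_loss(y, yhat, cfg))), rel=1e-12
        )

    def test_perfect_flat_prediction_cannot_reach_zero_with_margin(self):
        # all quantiles equal to y zeroes the prediction term but pays the
        # epsilon margin; both terms cannot vanish jointly
        cfg = LossConfig()
        y = np.array([10.0])
        yhat = np.full((1, 99), 10.0)
        assert total_loss(y, yhat, cfg) > 0.0
        assert total_loss(y, yhat, cfg) == pytest.approx(98e-6, rel=1e-9)

    def test_empty_batch_fatal(self):
        with pytest.raises(ValueError):
            total_loss(np.array([]), np.zeros((0, 99)), LossConfig())

    def test_gradient_finite_over_residual_sweep(self):
        # finite gradients everywhere incl. residual 0 and +/- delta
        cfg = LossConfig()
        delta = cfg.delta
        sweep = np.concatenate(
            [np.linspace(-100, 100, 41), [-delta, 0.0, delta]]
        )
        for r in sweep:
            yhat = Tensor(np.full((1, 99), 50.0 + r), requires_grad=True)
            loss = total_loss(np.array([50.0]), yhat, cfg)
            loss.backward()
            assert np.all(np.isfinite(yhat.grad))

    def test_autodiff_and_numpy_paths_agree(self):
        rng = np.random.default_rng(3)
        cfg = LossConfig()
        y = rng.normal(size=5) * 20 + 100
        yhat = y[:, None] + rng.normal(size=(5, 99)) * 3
        np_val = total_loss(y, yhat, cfg)
        ad_val = total_loss(y, Tensor(yhat, requires_grad=True), cfg)
        assert np_val == pytest.approx(float(ad_val.v), rel=1e-12)
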