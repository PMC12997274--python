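"""DP5q scoring: CDF construction, error score, molecular aggregation."""

import numpy as np
import pytest
from scipy.stats import norm

from dp5q.chem_io import ShiftSpectrum, molecule_from_smiles
from dp5q.losses import QuantileGrid
from dp5q.scoring import (
    cdf,
    error_score,
    molecule_dp5q,
    molecule_mae,
    predicted_median,
    repair_monotonic,
    score_pair,
)

GRID = QuantileGrid()


def gaussian_knots(mu=100.0, sigma=2.0):
    return mu + sigma * norm.ppf(GRID.array)


class TestRepair:
    def test_sorted_input_unchanged(self):
        v = np.linspace(0, 1, 99)
        assert np.array_equal(repair_monotonic(v), v)

    def test_sorts_crossings(self):
        assert np.array_equal(repair_monotonic(np.array([3.0, 1.0, 2.0])), [1.0, 2.0, 3.0])

    def test_preserves_value_multiset(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=99)
        assert sorted(v) == list(repair_monotonic(v))


class TestCdf:
    def test_knot_identity(self):
        q = gaussian_knots()
        for tau in (0.01, 0.25, 0.5, 0.77, 0.99):
            k = list(GRID.taus).index(tau)
            assert cdf(q, GRID, q[k]) == pytest.approx(tau, abs=1e-12)

    def test_linear_interpolation_between_knots(self):
        q = gaussian_knots()
        i40 = list(GRID.taus).index(0.40)
        x = 0.5 * (q[i40] + q[i40 + 1])
        assert cdf(q, GRID, x) == pytest.approx(0.405, abs=1e-12)

    def test_limits(self):
        q = gaussian_knots()
        assert cdf(q, GRID, -1e9) == 0.0
        assert cdf(q, GRID, 1e9) == 1.0

    def test_non_decreasing_in_x(self):
        q = repair_monotonic(np.random.default_rng(1).normal(100, 3, size=99))
        xs = np.linspace(80, 120, 2001)
        vals = cdf(q, GRID, xs)
        assert np.all(np.diff(vals) >= 0)

    def test_unrepaired_vector_rejected(self):
        with pytest.raises(ValueError):
            cdf(np.array([2.0, 1.0, 3.0]), QuantileGrid((0.25, 0.5, 0.75)), 1.5)


class TestErrorScore:
    def test_zero_error_gives_p_zero(self):
        q = gaussian_knots()
        assert error_score(q, GRID, q[49]) == 0.0

    def test_gaussian_one_sigma_closed_form(self):
        # P(|y - mu| = sigma) = Phi(1) - Phi(-1) ~ 0.6827
        q = gaussian_knots(mu=120.0, sigma=3.0)
        p = error_score(q, GRID, 123.0)
        assert p == pytest.approx(0.6827, abs=0.01)

    def test_far_tail_captures_all_mass(self):
        q = gaussian_knots()
        assert error_score(q, GRID, 100.0 + 50.0) == pytest.approx(1.0)

    def test_monotone_in_absolute_error(self):
        q = repair_monotonic(np.random.default_rng(3).normal(50, 2, size=99))
        med = predicted_median(q, GRID)
        ys = med + np.linspace(0, 20, 200)
        ps = [error_score(q, GRID, y) for y in ys]
        assert np.all(np.diff(ps) >= -1e-12)
        ps_neg = [error_score(q, GRID, med - (y - med)) for y in ys]
        assert np.allclose(ps, ps_neg)  # symmetric interval

    def test_matches_numerical_integration_oracle(self):
        # trapezoid integration of the implied piecewise density over
        # the interval [median - |e|, median + |e|]
        rng = np.random.default_rng(7)
        for _ in range(100):
            q = repair_monotonic(rng.normal(100, rng.uniform(0.5, 5), size=99))
            y = rng.uniform(90, 110)
            med = predicted_median(q, GRID)
            e = abs(med - y)
            if e == 0:
                continue
            xs = np.linspace(med - e, med + e, 10_000)
            fx = cdf(q, GRID, xs)
            numeric = fx[-1] - fx[0]  # integral of density = CDF difference
            trap = np.trapezoid(np.gradient(fx, xs), xs)
            assert error_score(q, GRID, y) == pytest.approx(numeric, abs=1e-12)
            assert error_score(q, GRID, y) == pytest.approx(trap, abs=1e-3)

    def test_degenerate_distribution_step_behaviour(self):
        q = np.full(99, 42.0)
        assert error_score(q, GRID, 42.0) == 0.0
        assert error_score(q, GRID, 43.0) == 1.0


class TestMolecularScore:
    def test_all_ones(self):
        assert molecule_dp5q(np.ones(7)) == 1.0

    def test_two_atom_closed_form(self):
        assert molecule_dp5q(np.array([1.0, 0.25])) == pytest.approx(0.5, rel=1e-12)

    def test_matches_naive_product_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            vals = rng.uniform(0.01, 1.0, size=rng.integers(1, 30))
            naive = np.prod(vals) ** (1.0 / len(vals))
            assert molecule_dp5q(vals) == pytest.approx(naive, abs=1e-12)

    def test_zero_propagates(self):
        assert molecule_dp5q(np.array([0.9, 0.0, 0.8])) == 0.0

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(13)
        vals = rng.uniform(0.05, 1.0, size=12)
        g = molecule_dp5q(vals)
        assert vals.min() <= g <= vals.max()

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            molecule_dp5q(np.array([]))


class TestMae:
    def test_perfect_predictions(self):
        spec = ShiftSpectrum([10.0, 20.0], assignment={0: 0, 1: 1})
        assert molecule_mae(np.array([10.0, 20.0]), spec) == 0.0

    def test_two_peak_mean(self):
        spec = ShiftSpectrum([10.0, 20.0], assignment={0: 0, 1: 1})
        assert molecule_mae(np.array([11.0, 23.0]), spec) == pytest.approx(2.0)

    def test_invariant_under_peak_reordering(self):
        a = ShiftSpectrum([10.0, 20.0], assignment={0: 0, 1: 1})
        b = ShiftSpectrum([20.0, 10.0], assignment={0: 1, 1: 0})
        preds = np.array([11.5, 22.0])
        assert molecule_mae(preds, a) == molecule_mae(preds, b)

    def test_unassigned_fatal(self):
        with pytest.raises(ValueError):
            molecule_mae(np.array([10.0]), ShiftSpectrum([10.0]))


class TestScorePair:
    def test_perfect_class_predictions_score_one(self):
        rec = molecule_from_smiles("CCO")
        q = np.stack([gaussian_knots(20.0, 2.0), gaussian_knots(60.0, 2.0)])
        spec = ShiftSpectrum([20.0, 60.0], assignment={0: 0, 1: 1})
        res = score_pair(rec, q, spec, GRID)
        assert res.molecular_dp5q == pytest.approx(1.0)
        assert res.molecular_mae == pytest.approx(0.0)
        assert res.n_atoms == 2

    def test_class_averaging_scores_once_per_class(self):
        rec = molecule_from_smiles("CC")  # one class of two carbons
        q = np.stack([gaussian_knots(10.0, 1.0), gaussian_knots(12.0, 1.0)])
        spec = ShiftSpectrum([11.0], assignment={0: 0})
        res = score_pair(rec, q, spec, GRID)
        assert res.n_atoms == 1
        assert res.atom_scores[0].predicted_median == pytest.approx(11.0)

    def test_auto_assignment_when_spectrum_unassigned(self):
        rec = molecule_from_smiles("CCO")
        q = np.stack([gaussian_knots(18.0, 2.0), gaussian_knots(58.0, 2.0)])
        spec = ShiftSpectrum([57.5, 18.5])  # reversed order, no assignment
        res = score_pair(rec, q, spec, GRID)
        assert res.molecular_mae == pytest.approx(0.5)
        assert res.molecular_dp5q > 0.5
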