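"""Grey model families: design construction, least squares, time response,
degeneracy structure, restoration error bound and prediction growth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greycast import (
    GM11,
    NGBM,
    DampedGM11,
    DampedNGBM,
    builtin_fixture,
    build_design,
    damping_accumulate,
    damping_restore,
    generate_synthetic,
    least_squares,
    make_forecaster,
    mean_sequence,
)
from greycast.models import (
    DegenerateModelError,
    GreyModelError,
    InvalidExponentError,
    NonPositiveBackgroundError,
    PositivityError,
    RankDeficientError,
)


def _refine_1d(f, lo, hi, rounds=8, grid=33):
    """Grid-refine the minimizer of a convex scalar function on [lo, hi].

    Each round keeps one grid spacing on either side of the best point, so
    the true minimizer can never escape the bracket.  Returns the best grid
    point, its value, and the final resolution."""
    for _ in range(rounds):
        xs = np.linspace(lo, hi, grid)
        vals = np.array([f(x) for x in xs])
        i = int(np.argmin(vals))
        lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, grid - 1)]
    return xs[i], vals[i], (hi - lo)


def brute_force_lstsq(B, Y):
    """Independent least-squares oracle: nested 1-D grid refinement.

    For each candidate development coefficient a, the optimal action
    quantity b is a weighted mean of (Y - a*B[:,0]) / B[:,1], so it lies
    between the extremes of that ratio; the inner search refines b on that
    bracket, the outer search refines a.  Only convexity of the residual
    sum of squares is assumed — no matrix algebra."""
    z_col, p_col = B[:, 0], B[:, 1]

    def sse(a, b):
        r = Y - a * z_col - b * p_col
        return float(r @ r)

    def best_b(a):
        ratio = (Y - a * z_col) / p_col
        return _refine_1d(lambda b: sse(a, b), ratio.min() - 1.0, ratio.max() + 1.0)

    a_hat, _, da = _refine_1d(lambda a: best_b(a)[1], -60.0, 60.0)
    b_hat, _, db = best_b(a_hat)
    # b*(a) drifts with a in a correlated valley; widen its resolution accordingly
    db += float(np.max(np.abs(z_col / p_col))) * da
    return np.array([a_hat, b_hat]), np.array([da, db]) + 1e-9


class TestBuildDesign:
    def test_classical_hand_example(self):
        acc = damping_accumulate([1, 2, 3], 1.0).values
        B, Y = build_design(acc, mean_sequence(acc), alpha=0.0)
        np.testing.assert_allclose(B, [[-2.0, 1.0], [-4.5, 1.0]])
        np.testing.assert_allclose(Y, [2.0, 3.0])

    def test_zeta_one_response_telescopes_to_original(self, jiangsu):
        x = jiangsu.to_array()[:8]
        acc = damping_accumulate(x, 1.0).values
        _, Y = build_design(acc, mean_sequence(acc), alpha=0.4)
        np.testing.assert_allclose(Y, x[1:], rtol=1e-12)

    def test_alpha_zero_gives_unit_column(self, nanjing):
        acc = damping_accumulate(nanjing.to_array(), 0.9).values
        B, _ = build_design(acc, mean_sequence(acc), alpha=0.0)
        np.testing.assert_array_equal(B[:, 1], np.ones(len(acc) - 1))

    def test_fractional_power_needs_positive_background(self):
        with pytest.raises(NonPositiveBackgroundError):
            build_design([1.0, 2.0, 3.0, 4.0], [0.5, -1.0, 3.5], alpha=0.5)


class TestLeastSquares:
    def test_exact_square_system(self):
        B = np.array([[-2.0, 1.0], [-4.5, 1.0]])
        Y = np.array([2.0, 3.0])
        a, b = least_squares(B, Y)
        np.testing.assert_allclose(B @ [a, b], Y, rtol=1e-12)

    def test_agrees_with_normal_equations(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            z = rng.uniform(1, 50, size=7)
            B = np.column_stack([-z, z**0.3])
            Y = rng.uniform(1, 20, size=7)
            sol = np.linalg.solve(B.T @ B, B.T @ Y)
            np.testing.assert_allclose(least_squares(B, Y), sol, rtol=1e-8)

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            z = rng.uniform(1, 10, size=6)
            B = np.column_stack([-z, z**0.5])
            Y = rng.uniform(1, 5, size=6)
            approx, resolution = brute_force_lstsq(B, Y)
            exact = np.array(least_squares(B, Y))
            assert np.all(np.abs(exact - approx) <= resolution)

    def test_rank_deficient(self):
        B = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(RankDeficientError):
            least_squares(B, np.array([1.0, 2.0, 3.0]))


class TestFit:
    def test_published_parameters_nanjing(self, nanjing, split):
        model = DampedNGBM(alpha=-0.0468, zeta=0.9677).fit(nanjing.train_values(split))
        assert model.a_ == pytest.approx(-0.0558, abs=1e-3)
        assert model.b_ == pytest.approx(407.1498, rel=5e-4)

    @pytest.mark.parametrize("alpha", [-0.3, 0.0, 0.45])
    @pytest.mark.parametrize("name", ["china_birth_rate", "jiangsu_registered", "nanjing_male"])
    def test_damped_family_degenerates_at_zeta_one(self, name, alpha, split):
        """zeta = 1 collapses DA-NGBM onto NGBM (and, at alpha = 0, GM(1,1))
        output-for-output."""
        train = builtin_fixture(name).train_values(split)
        damped = DampedNGBM(alpha=alpha, zeta=1.0).fit(train)
        classical = NGBM(alpha=alpha).fit(train)
        assert damped.a_ == pytest.approx(classical.a_, rel=1e-10)
        assert damped.b_ == pytest.approx(classical.b_, rel=1e-10)
        np.testing.assert_allclose(
            damped.fitted_values_, classical.fitted_values_, rtol=1e-10
        )
        np.testing.assert_allclose(damped.predict(3), classical.predict(3), rtol=1e-10)
        if alpha == 0.0:
            gm = GM11().fit(train)
            np.testing.assert_allclose(damped.predict(3), gm.predict(3), rtol=1e-10)
            da_gm = DampedGM11(zeta=1.0).fit(train)
            np.testing.assert_allclose(da_gm.predict(3), gm.predict(3), rtol=1e-10)

    def test_alpha_one_rejected(self, birth_rate, split):
        with pytest.raises(InvalidExponentError):
            DampedNGBM(alpha=1.0, zeta=0.9).fit(birth_rate.train_values(split))

    def test_too_short(self):
        with pytest.raises(GreyModelError):
            GM11().fit([1.0, 2.0, 3.0])

    def test_zero_development_coefficient_rejected(self):
        flat = generate_synthetic(a=0.0, b=5.0, alpha=0.0, zeta=1.0, n=8)
        with pytest.raises(DegenerateModelError):
            GM11().fit(flat.to_array())

    def test_unfitted_predict_raises(self):
        with pytest.raises(GreyModelError):
            GM11().predict(2)


class TestTimeResponseAndForecast:
    def test_anchor_at_first_observation(self, jiangsu, split):
        model = DampedNGBM(alpha=0.0114, zeta=0.9458).fit(jiangsu.train_values(split))
        assert model.time_response(0) == pytest.approx(model.x1_, rel=1e-12)
        assert model.fitted_values_[0] == model.x1_

    def test_gm11_matches_closed_form(self, nanjing, split):
        """At alpha = 0, zeta = 1 the response is the textbook GM(1,1)
        exponential b/a + (x1 - b/a) e^(-a k)."""
        train = nanjing.train_values(split)
        model = GM11().fit(train)
        k = np.arange(10)
        expected = model.b_ / model.a_ + (model.x1_ - model.b_ / model.a_) * np.exp(
            -model.a_ * k
        )
        np.testing.assert_allclose(model.time_response(k), expected, rtol=1e-12)

    def test_published_restored_prediction(self, birth_rate, split):
        model = DampedNGBM(alpha=0.0975, zeta=0.7359).fit(birth_rate.train_values(split))
        assert model.predict(1)[0] == pytest.approx(10.66, abs=0.01)

    def test_zero_horizon(self, birth_rate, split):
        model = GM11().fit(birth_rate.train_values(split))
        result = model.forecast(0)
        assert result.predicted.size == 0
        assert result.fitted.size == split.train_length

    def test_positivity_guard(self, nanjing, split):
        model = DampedNGBM(alpha=0.5, zeta=0.9).fit(nanjing.train_values(split))
        model.a_, model.b_ = 0.5, -1.0  # force a response base that turns negative
        with pytest.raises(PositivityError):
            model.predict(40)

    def test_make_forecaster_validation(self):
        with pytest.raises(GreyModelError):
            make_forecaster("gm11", alpha=0.5)
        with pytest.raises(GreyModelError):
            make_forecaster("ngbm", zeta=0.5)
        with pytest.raises(GreyModelError):
            make_forecaster("verhulst")


class TestRestorationErrorBound:
    @given(
        zeta=st.floats(min_value=0.1, max_value=1.0),
        eps=st.floats(min_value=1e-6, max_value=10.0),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=60, derandomize=True)
    def test_perturbation_bound(self, zeta, eps, seed):
        """Perturbing the accumulated response by at most eps perturbs the
        restored value at step k by at most 2 * zeta**(k-1) * eps."""
        rng = np.random.default_rng(seed)
        acc = np.cumsum(rng.uniform(0.5, 5.0, size=10))
        delta = rng.uniform(-eps, eps, size=10)
        base = damping_restore(acc, zeta)
        shifted = damping_restore(acc + delta, zeta)
        k = np.arange(1, 11)
        bound = 2.0 * zeta ** (k - 1) * eps
        bound[0] = eps  # first value is copied, not differenced
        assert np.all(np.abs(shifted - base) <= bound + 1e-12)


class TestPredictionGrowthInZeta:
    @pytest.mark.parametrize(
        "name, alpha, zeta",
        [
            ("china_birth_rate", 0.0975, 0.7359),
            ("jiangsu_registered", 0.0114, 0.9458),
            ("nanjing_male", -0.0468, 0.9677),
        ],
    )
    def test_growth_rate_monotone_in_zeta(self, name, alpha, zeta, split):
        """For a fitted model, the out-of-sample growth ratio of restored
        predictions increases with the damping coefficient used in
        restoration."""
        series = builtin_fixture(name)
        model = DampedNGBM(alpha=alpha, zeta=zeta).fit(series.train_values(split))
        acc = model.time_response(np.arange(split.train_length + 2))
        ratios = []
        for z in np.linspace(0.3, 1.0, 15):
            restored = damping_restore(acc, z)
            ratios.append(restored[-1] / restored[-2])
        assert np.all(np.diff(ratios) > 0)


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "cls, kwargs",
        [
            (GM11, dict(a=-0.06, b=80.0, alpha=0.0, zeta=1.0)),
            (DampedNGBM, dict(a=-0.05, b=30.0, alpha=0.25, zeta=0.7)),
        ],
    )
    def test_noiseless_fit_reproduces_generator(self, cls, kwargs):
        series = generate_synthetic(n=10, **kwargs)
        free = {k: kwargs[k] for k in cls._free_params}
        model = cls(**free).fit(series.to_array())
        assert model.a_ == pytest.approx(kwargs["a"], rel=1e-6)
        assert model.b_ == pytest.approx(kwargs["b"], rel=1e-6)
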