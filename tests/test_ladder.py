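import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptrex.errors import (
    InfeasibleConstraintError,
    InsufficientDataError,
    InvalidArgumentError,
)
from adaptrex.ladder import (
    FractionProfile,
    TemperatureLadder,
    VisitHistogram,
    _pava_nonincreasing,
    adapt_temperatures,
    enforce_spacing_constraint,
    fraction_cold,
    geometric_ladder,
    interpolate_inverse,
    spacing_ratio,
    target_fraction,
)

from conftest import linear_index_histogram


def grid_inverse(temps, f, target, n_grid=10_000):
    """Brute-force inversion oracle: dense grid argmin over |f_hat - target|."""
    grid = np.linspace(temps[0], temps[-1], n_grid)
    fhat = np.interp(grid, temps, f)
    return grid[np.argmin(np.abs(fhat - target))]


class TestGeometricLadder:
    def test_benchmark_bounds_exact(self):
        lad = geometric_ladder(275.0, 350.0, 16)
        assert lad.temps[0] == 275.0
        assert lad.temps[-1] == 350.0
        assert lad.n == 16

    def test_two_point_ladder(self):
        lad = geometric_ladder(3.0, 6.0, 2)
        assert lad.temps.tolist() == [3.0, 6.0]

    def test_closed_form_interior(self):
        lad = geometric_ladder(275.0, 350.0, 16)
        expected = 275.0 * (350.0 / 275.0) ** (1.0 / 15.0)
        assert lad.temps[1] == pytest.approx(expected, rel=1e-14)

    def test_constant_ratio(self):
        lad = geometric_ladder(275.0, 350.0, 16)
        ratios = lad.temps[1:] / lad.temps[:-1]
        assert np.all(np.abs(ratios - spacing_ratio(lad)) < 1e-12)

    @pytest.mark.parametrize(
        "args", [(0.0, 350.0, 16), (-1.0, 350.0, 16), (350.0, 275.0, 16),
                 (275.0, 275.0, 16), (275.0, 350.0, 1)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(InvalidArgumentError):
            geometric_ladder(*args)

    @given(
        t_min=st.floats(1e-3, 1e3),
        span=st.floats(1.01, 50.0),
        n=st.integers(2, 64),
    )
    @settings(max_examples=50, deadline=None)
    def test_property_ratio_and_endpoints(self, t_min, span, n):
        lad = geometric_ladder(t_min, t_min * span, n)
        assert lad.temps[0] == t_min
        assert lad.temps[-1] == t_min * span
        ratios = lad.temps[1:] / lad.temps[:-1]
        assert np.all(np.abs(ratios / spacing_ratio(lad) - 1.0) < 1e-12)


class TestSpacingRatio:
    def test_closed_form(self):
        lad = geometric_ladder(275.0, 350.0, 16)
        assert spacing_ratio(lad) == pytest.approx((350.0 / 275.0) ** (1 / 15), rel=1e-14)

    def test_inverse_of_construction(self):
        r = 1.07
        temps = 2.0 * r ** np.arange(9)
        assert spacing_ratio(TemperatureLadder(temps)) == pytest.approx(r, rel=1e-12)

    def test_n2(self):
        lad = geometric_ladder(10.0, 30.0, 2)
        assert spacing_ratio(lad) == pytest.approx(3.0)


class TestFractionCold:
    def test_direct_arithmetic(self):
        hist = VisitHistogram(temps=[300.0], n_cold=[3], n_hot=[1])
        assert fraction_cold(hist).f[0] == pytest.approx(0.75)

    def test_all_cold(self):
        hist = VisitHistogram(temps=[300.0], n_cold=[7], n_hot=[0])
        assert fraction_cold(hist).f[0] == 1.0

    def test_empty_window_undefined(self):
        hist = VisitHistogram(temps=[300.0], n_cold=[0], n_hot=[0])
        assert np.isnan(fraction_cold(hist).f[0])

    @given(
        n_cold=st.integers(0, 1000),
        n_hot=st.integers(0, 1000),
        extra=st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_cold_visit_monotonicity(self, n_cold, n_hot, extra):
        before = fraction_cold(
            VisitHistogram(temps=[1.0], n_cold=[n_cold], n_hot=[n_hot])
        ).f[0]
        after = fraction_cold(
            VisitHistogram(temps=[1.0], n_cold=[n_cold + extra], n_hot=[n_hot])
        ).f[0]
        assert np.isnan(before) or after >= before
        assert 0.0 <= after <= 1.0


class TestTargetFraction:
    @pytest.mark.parametrize("i,n,expected", [(0, 16, 1.0), (15, 16, 0.0), (5, 11, 0.5)])
    def test_values(self, i, n, expected):
        assert target_fraction(i, n) == pytest.approx(expected)

    @pytest.mark.parametrize("i", [-1, 16])
    def test_out_of_range(self, i):
        with pytest.raises(InvalidArgumentError):
            target_fraction(i, 16)


class TestPava:
    def test_matches_sklearn_isotonic(self, rng):
        from sklearn.isotonic import IsotonicRegression

        for _ in range(50):
            y = rng.random(rng.integers(2, 20))
            ours = _pava_nonincreasing(y)
            ref = IsotonicRegression(increasing=False).fit_transform(
                np.arange(y.size), y
            )
            np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestInterpolateInverse:
    def test_exact_knot(self):
        prof = FractionProfile(temps=[275.0, 310.0, 350.0], f=[1.0, 0.5, 0.0])
        assert interpolate_inverse(prof, 0.5) == pytest.approx(310.0)

    def test_two_point_linear(self):
        prof = FractionProfile(temps=[275.0, 350.0], f=[1.0, 0.0])
        assert interpolate_inverse(prof, 0.25) == pytest.approx(331.25)

    def test_nonmonotone_matches_grid_oracle(self):
        temps = np.array([275.0, 300.0, 325.0, 350.0])
        f = np.array([1.0, 0.2, 0.4, 0.0])
        g = _pava_nonincreasing(f)  # pools the violator to a 0.3 plateau
        for target in (0.9, 0.5, 0.1):
            expected = grid_inverse(temps, g, target)
            got = interpolate_inverse(FractionProfile(temps=temps, f=f), target)
            assert abs(got - expected) < (350.0 - 275.0) / 10_000 * 2
        # a target on the plateau inverts ambiguously in T; both answers must
        # hit the target in f to within grid resolution
        got = interpolate_inverse(FractionProfile(temps=temps, f=f), 0.3)
        assert abs(np.interp(got, temps, g) - 0.3) < 1e-12

    def test_randomized_monotone_profiles_match_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(3, 12)
            temps = np.sort(rng.uniform(200, 400, n))
            temps += np.arange(n) * 1e-6  # ensure distinct
            f = np.sort(rng.random(n))[::-1]
            prof = FractionProfile(temps=temps, f=f)
            target = rng.random()
            got = interpolate_inverse(prof, target)
            expected = grid_inverse(temps, _pava_nonincreasing(f), target)
            assert abs(got - expected) < (temps[-1] - temps[0]) / 10_000 * 2

    def test_undefined_entries_excluded(self):
        prof = FractionProfile(
            temps=[275.0, 300.0, 350.0], f=[1.0, np.nan, 0.0]
        )
        assert interpolate_inverse(prof, 0.5) == pytest.approx(312.5)

    def test_insufficient_data(self):
        prof = FractionProfile(temps=[275.0, 350.0], f=[1.0, np.nan])
        with pytest.raises(InsufficientDataError):
            interpolate_inverse(prof, 0.5)


class TestEnforceSpacingConstraint:
    def test_geometric_unchanged(self):
        lad = geometric_ladder(275.0, 350.0, 16)
        r = spacing_ratio(lad)
        out = enforce_spacing_constraint(lad.temps, r, 275.0, 350.0)
        np.testing.assert_allclose(out, lad.temps, rtol=1e-12)

    def test_interior_clustered_at_t_max(self):
        n = 8
        r = spacing_ratio(geometric_ladder(275.0, 350.0, n))
        temps = np.concatenate([[275.0], np.full(n - 2, 350.0), [350.0]])
        out = enforce_spacing_constraint(temps, r, 275.0, 350.0)
        assert out[0] == 275.0
        assert out[-1] == 350.0
        ratios = out[1:] / out[:-1]
        assert np.all(ratios <= r * r * (1 + 1e-12))
        assert np.all(np.diff(out) > 0)

    def test_single_oversized_gap(self):
        lad = geometric_ladder(275.0, 350.0, 16)
        r = spacing_ratio(lad)
        temps = lad.temps.copy()
        temps[8:] *= r  # creates one gap of ratio r**2 ... push further
        temps[8:] = np.minimum(temps[8:] * r, 350.0)
        temps[-1] = 350.0
        temps = np.sort(temps)
        out = enforce_spacing_constraint(temps, r, 275.0, 350.0)
        ratios = out[1:] / out[:-1]
        assert np.all(ratios <= r * r * (1 + 1e-12))

    def test_infeasible(self):
        with pytest.raises(InfeasibleConstraintError):
            enforce_spacing_constraint([1.0, 2.0, 100.0], 1.01, 1.0, 100.0)

    def test_randomized_property(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 20))
            t_min, span = 10 ** rng.uniform(-1, 2), rng.uniform(1.2, 20.0)
            t_max = t_min * span
            r = spacing_ratio(geometric_ladder(t_min, t_max, n))
            temps = np.sort(rng.uniform(t_min, t_max, n))
            temps[0], temps[-1] = t_min, t_max
            out = enforce_spacing_constraint(temps, r, t_min, t_max)
            assert out[0] == t_min and out[-1] == t_max
            assert np.all(np.diff(out) > 0)
            assert np.all(out[1:] / out[:-1] <= r * r * (1 + 1e-12))


class TestAdaptTemperatures:
    def test_idempotent_on_index_linear_profile(self, bench_ladder):
        hist = linear_index_histogram(bench_ladder)
        new = adapt_temperatures(bench_ladder, hist)
        np.testing.assert_allclose(new.temps, bench_ladder.temps, atol=1e-9)

    def test_step_profile_concentrates_near_tc(self, bench_ladder):
        tc = 310.0
        n = bench_ladder.n
        f_exact = (bench_ladder.temps < tc).astype(float)
        total = 100
        hist = VisitHistogram(
            temps=bench_ladder.temps.copy(),
            n_cold=(f_exact * total).astype(np.int64),
            n_hot=((1 - f_exact) * total).astype(np.int64),
        )
        new = adapt_temperatures(bench_ladder, hist)
        r = spacing_ratio(bench_ladder)
        ratios = new.temps[1:] / new.temps[:-1]
        assert np.all(ratios <= r * r * (1 + 1e-12))
        # interior temperatures pile up around the step location
        interior = new.temps[1:-1]
        assert np.sum(np.abs(interior - tc) < 15.0) > np.sum(
            np.abs(bench_ladder.temps[1:-1] - tc) < 15.0
        )

    def test_temperature_linear_profile_matches_grid_oracle(self, bench_ladder):
        # f linear in temperature (not index) -> new temps equally spaced in T
        n = bench_ladder.n
        t = bench_ladder.temps
        f = (t[-1] - t) / (t[-1] - t[0])
        per = 1000
        n_cold = np.round(f * per).astype(np.int64)
        hist = VisitHistogram(temps=t.copy(), n_cold=n_cold, n_hot=per - n_cold)
        new = adapt_temperatures(bench_ladder, hist)

        f_meas = n_cold / per
        grid = np.linspace(t[0], t[-1], 1_000_000)
        fhat = np.interp(grid, t, f_meas)
        expected = [t[0]]
        for i in range(1, n - 1):
            target = 1.0 - i / (n - 1)
            expected.append(grid[np.argmin(np.abs(fhat - target))])
        expected.append(t[-1])
        np.testing.assert_allclose(new.temps, expected, atol=0.01)

    def test_unvisited_endpoint_raises(self, bench_ladder):
        hist = linear_index_histogram(bench_ladder)
        hist.n_cold[0] = 0
        hist.n_hot[0] = 0
        with pytest.raises(InsufficientDataError):
            adapt_temperatures(bench_ladder, hist)

    def test_randomized_histograms_keep_invariants(self, bench_ladder, rng):
        r = spacing_ratio(bench_ladder)
        for _ in range(100):
            hist = VisitHistogram(
                temps=bench_ladder.temps.copy(),
                n_cold=rng.integers(1, 100, bench_ladder.n),
                n_hot=rng.integers(1, 100, bench_ladder.n),
            )
            new = adapt_temperatures(bench_ladder, hist)
            assert new.temps[0] == bench_ladder.t_min
            assert new.temps[-1] == bench_ladder.t_max
            assert np.all(np.diff(new.temps) > 0)
            assert np.all(new.temps[1:] / new.temps[:-1] <= r * r * (1 + 1e-12))
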