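"""Penalized FLM engine: basis, IRLS reductions, invariants, shape tools."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sizeflm.flm import (
    CoefficientFunction,
    FunctionalLinearModel,
    _cr_eval,
    _cr_penalty,
    age_shape_label,
    build_basis,
    classify_shape,
    fit_age_model,
    is_unimodal,
)
from sizeflm.vital_rates import SizeGrid, VitalRateTable


@pytest.fixture
def grid14():
    return SizeGrid(np.linspace(2.0, 4.8, 15))


def single_bin_design(seed=3, n=80):
    rng = np.random.default_rng(seed)
    w = rng.poisson(15, n).astype(float)
    grid = SizeGrid(np.array([2.0, 4.8]))
    col = np.repeat(["a", "b", "c", "d"], n // 4)
    C = pd.get_dummies(col).to_numpy(float)
    return rng, w, grid, col, np.hstack([C, w[:, None]])


class TestBasis:
    def test_full_column_rank_at_bin_centers(self, grid14):
        basis = build_basis(grid14, 5)
        assert basis.basis_matrix.shape == (14, 5)
        assert np.linalg.matrix_rank(basis.basis_matrix) == 5

    def test_cardinal_property_at_knots(self, grid14):
        basis = build_basis(grid14, 4)
        M = _cr_eval(basis.knots, basis.knots)
        assert np.allclose(M, np.eye(4), atol=1e-10)

    def test_penalty_null_space_is_linear_functions(self, grid14):
        basis = build_basis(grid14, 5)
        for v in (np.ones(5), basis.knots, 2.0 - 0.5 * basis.knots):
            assert abs(v @ basis.penalty_matrix @ v) < 1e-9

    def test_oscillation_penalized_more_than_line(self, grid14):
        basis = build_basis(grid14, 5)
        wiggle = np.sin(np.linspace(0, 2 * np.pi, 5))
        line = np.linspace(-1, 1, 5)
        assert wiggle @ basis.penalty_matrix @ wiggle > \
            line @ basis.penalty_matrix @ line

    def test_knot_cap_enforced(self, grid14):
        with pytest.raises(ValueError, match="cap"):
            build_basis(grid14, 6)

    def test_more_knots_than_bins_rejected(self):
        grid = SizeGrid(np.linspace(2.0, 4.0, 4))
        with pytest.raises(ValueError, match="bins"):
            build_basis(grid, 5)

    def test_evaluation_outside_range_errors(self, grid14):
        basis = build_basis(grid14, 5)
        with pytest.raises(ValueError, match="outside"):
            basis.evaluate(5.5)

    def test_penalty_consistent_with_quadrature(self):
        # quadratic f on [0,1]: integral of (f'')^2 for f = x^2 is 4
        knots = np.linspace(0.0, 1.0, 5)
        S = _cr_penalty(knots)
        vals = knots**2
        # natural spline interpolant of x^2 is not exactly x^2, so compare
        # against quadrature of the interpolant's own second derivative
        t = np.linspace(0, 1, 2001)
        f = _cr_eval(knots, t) @ vals
        d2 = np.gradient(np.gradient(f, t), t)
        quad = np.trapezoid(d2[5:-5] ** 2, t[5:-5])
        assert abs(vals @ S @ vals - quad) / quad < 0.05


class TestScalarReduction:
    """Single bin + zero penalty collapses to an ordinary GLM."""

    def test_gaussian_matches_ols(self):
        rng, w, grid, col, Xd = single_bin_design()
        y = 1.0 + 0.3 * w + rng.normal(0, 0.5, len(w))
        est = FunctionalLinearModel(grid=grid, family="gaussian", lam=0.0)
        est.fit(w[:, None], y, colony_ids=col)
        ref = sm.OLS(y, Xd).fit()
        mine = np.r_[[est.intercepts_[c] for c in est.colonies_], est.coef_]
        assert np.allclose(mine, ref.params, rtol=1e-6)

    def test_binomial_matches_glm(self):
        rng, w, grid, col, Xd = single_bin_design(seed=4)
        p = 1 / (1 + np.exp(-(-2 + 0.1 * w)))
        trials = rng.integers(5, 9, len(w))
        s = rng.binomial(trials, p)
        Y = np.column_stack([s, trials - s]).astype(float)
        est = FunctionalLinearModel(grid=grid, family="binomial", lam=0.0)
        est.fit(w[:, None], Y, colony_ids=col)
        ref = sm.GLM(Y, Xd, family=sm.families.Binomial()).fit(tol=1e-12)
        mine = np.r_[[est.intercepts_[c] for c in est.colonies_], est.coef_]
        assert np.max(np.abs((mine - ref.params) / ref.params)) < 1e-6

    def test_negative_binomial_matches_glm_with_offset(self):
        rng, w, grid, col, Xd = single_bin_design(seed=5)
        off = rng.choice([6.0, 7.0, 8.0], len(w))
        mu = np.exp(0.2 + 0.05 * w) * off
        y = rng.negative_binomial(1 / 0.3, (1 / 0.3) / (1 / 0.3 + mu))
        est = FunctionalLinearModel(grid=grid, family="negative_binomial",
                                    lam=0.0, nb_alpha=0.3)
        est.fit(w[:, None], y, colony_ids=col, offset_days=off)
        ref = sm.GLM(y, Xd, family=sm.families.NegativeBinomial(alpha=0.3),
                     offset=np.log(off)).fit(tol=1e-12)
        mine = np.r_[[est.intercepts_[c] for c in est.colonies_], est.coef_]
        assert np.max(np.abs((mine - ref.params) / ref.params)) < 1e-6
        assert np.isclose(est.loglik_, ref.llf, rtol=1e-8)


def functional_dataset(seed=7, n_colonies=7, n_weeks=12, beta=None,
                       family="gaussian", grid=None):
    """Composition rows with a known coefficient-function signal."""
    rng = np.random.default_rng(seed)
    grid = grid or SizeGrid(np.linspace(2.0, 4.8, 15))
    centers = grid.bin_centers
    if beta is None:
        beta = 0.3 * (centers - centers.mean())
    rows, cols, ys = [], [], []
    for c in range(n_colonies):
        b0 = rng.normal(0, 0.3)
        for _ in range(n_weeks):
            counts = rng.poisson(1.6, grid.n_bins).astype(float)
            eta = b0 + counts @ beta
            rows.append(counts)
            cols.append(f"col{c}")
            ys.append(eta + rng.normal(0, 0.5))
    return grid, np.array(rows), np.array(cols), np.array(ys)


class TestPenalizedFit:
    def test_recovers_known_coefficient_function(self):
        grid, X, cols, y = functional_dataset()
        est = FunctionalLinearModel(grid=grid, family="gaussian").fit(
            X, y, colony_ids=cols)
        fitted = est.basis_.basis_matrix @ est.coef_
        truth = 0.3 * (grid.bin_centers - grid.bin_centers.mean())
        assert np.corrcoef(fitted, truth)[0, 1] > 0.9

    def test_edf_nonincreasing_in_lambda(self):
        grid, X, cols, y = functional_dataset(seed=8)
        edfs = []
        for lam in (0.0, 0.1, 10.0, 1e3, 1e6):
            est = FunctionalLinearModel(grid=grid, family="gaussian",
                                        lam=lam).fit(X, y, colony_ids=cols)
            edfs.append(est.edf_)
        assert all(a >= b - 1e-8 for a, b in zip(edfs[:-1], edfs[1:]))

    def test_heavy_smoothing_reaches_penalty_null_space(self):
        grid, X, cols, y = functional_dataset(seed=9)
        est = FunctionalLinearModel(grid=grid, family="gaussian",
                                    lam=1e9).fit(X, y, colony_ids=cols)
        # coefficient function collapses to a line across the knots
        vals = est.coef_
        second_diff = np.diff(vals, 2)
        assert np.max(np.abs(second_diff)) < 1e-3 * (np.ptp(vals) + 1e-9)

    def test_offset_scaling_shifts_intercepts_only(self):
        rng = np.random.default_rng(11)
        grid = SizeGrid(np.linspace(2.0, 4.8, 15))
        X = rng.poisson(1.5, (60, 14)).astype(float)
        cols = np.repeat([f"c{i}" for i in range(6)], 10)
        off = rng.choice([6.0, 7.0, 8.0], 60)
        mu = np.exp(0.5 + 0.02 * X.sum(axis=1)) * off
        y = rng.negative_binomial(5, 5 / (5 + mu))
        kw = dict(grid=grid, family="negative_binomial", lam=1.0,
                  nb_alpha=0.2)
        e1 = FunctionalLinearModel(**kw).fit(X, y, colony_ids=cols,
                                             offset_days=off)
        e2 = FunctionalLinearModel(**kw).fit(X, y, colony_ids=cols,
                                             offset_days=off * 3.0)
        for c in e1.colonies_:
            assert np.isclose(e1.intercepts_[c] - e2.intercepts_[c],
                              np.log(3.0), atol=1e-6)
        assert np.allclose(e1.coef_, e2.coef_, atol=1e-6)

    def test_interval_trials_match_day_expanded_bernoulli(self):
        """Binomial day-trial rows carry the same likelihood information as
        one Bernoulli row per day (up to the binomial coefficient)."""
        rng = np.random.default_rng(13)
        n = 40  # cells
        grid = SizeGrid(np.array([2.0, 4.8]))
        w = rng.poisson(12, n).astype(float)
        days = rng.integers(4, 9, n)
        p = 1 / (1 + np.exp(-(2.0 + 0.05 * w)))
        died = rng.random(n) > p**days
        succ = np.where(died, days - 1, days)
        fail = np.where(died, 1, 0)
        Y = np.column_stack([succ, fail]).astype(float)
        cols = np.repeat(["a", "b"], n // 2)
        est = FunctionalLinearModel(grid=grid, family="binomial", lam=0.0)
        est.fit(w[:, None], Y, colony_ids=cols)
        # expand to one Bernoulli trial per day
        reps = days
        w_x = np.repeat(w, reps)
        col_x = np.repeat(cols, reps)
        y_x = np.concatenate([
            np.r_[np.ones(int(s)), np.zeros(int(f))]
            for s, f in zip(succ, fail)])
        Y_x = np.column_stack([y_x, 1 - y_x])
        est_x = FunctionalLinearModel(grid=grid, family="binomial", lam=0.0)
        est_x.fit(w_x[:, None], Y_x, colony_ids=col_x)
        mine = np.r_[[est.intercepts_[c] for c in est.colonies_], est.coef_]
        other = np.r_[[est_x.intercepts_[c] for c in est_x.colonies_],
                      est_x.coef_]
        assert np.allclose(mine, other, rtol=1e-6)
        # log-likelihoods differ exactly by the binomial coefficients
        from scipy.special import gammaln
        const = float(np.sum(gammaln(days + 1) - gammaln(succ + 1)
                             - gammaln(fail + 1)))
        assert np.isclose(est.loglik_ - est_x.loglik_, const, atol=1e-6)

    def test_null_signal_keeps_pvalue_honest(self):
        """With no composition effect, the smooth p-value at the .01 cutoff
        retains the smooth in well under 10% of replicates."""
        hits = 0
        n_rep = 40
        for i in range(n_rep):
            grid, X, cols, y = functional_dataset(
                seed=100 + i, beta=np.zeros(14))
            est = FunctionalLinearModel(grid=grid, family="gaussian").fit(
                X, y, colony_ids=cols)
            if est.smooth_pvalue_ < 0.01:
                hits += 1
        assert hits / n_rep <= 0.10


class TestShapeTools:
    def cf_from_values(self, grid, values, se=0.01):
        basis = build_basis(grid, min(5, len(values)))
        # cardinal basis: coefficients are knot values
        cov = np.eye(basis.n_knots) * se**2
        return CoefficientFunction(basis, np.asarray(values, float), cov)

    def test_monotone_is_unimodal(self, grid14):
        cf = self.cf_from_values(grid14, [-1, -0.5, 0, 0.5, 1])
        assert is_unimodal(cf, grid14)

    def test_single_peak_is_unimodal(self, grid14):
        cf = self.cf_from_values(grid14, [0, 0.8, 1.0, 0.8, 0])
        assert is_unimodal(cf, grid14)

    def test_two_peaks_fail_screen(self, grid14):
        cf = self.cf_from_values(grid14, [0, 1.0, -0.8, 1.0, 0])
        assert not is_unimodal(cf, grid14)

    def test_constant_passes_screen(self, grid14):
        cf = self.cf_from_values(grid14, [0.4] * 5)
        assert is_unimodal(cf, grid14)

    def test_n_eval_floor(self, grid14):
        cf = self.cf_from_values(grid14, [0.4] * 5)
        with pytest.raises(ValueError):
            is_unimodal(cf, grid14, n_eval=10)

    def test_positive_increasing_labels(self, grid14):
        cf = self.cf_from_values(grid14, [0.2, 0.4, 0.6, 0.8, 1.0])
        assert classify_shape(cf, grid14) == ("positive", "increasing")

    def test_mixed_increasing_labels(self, grid14):
        cf = self.cf_from_values(grid14, [-0.5, -0.25, 0, 0.25, 0.5])
        assert classify_shape(cf, grid14) == ("mixed", "increasing")

    def test_indistinguishable_from_zero_is_none(self, grid14):
        cf = self.cf_from_values(grid14, [0.01, -0.01, 0.0, 0.01, -0.01],
                                 se=10.0)
        assert classify_shape(cf, grid14) == ("none", "none")

    def test_grid_values_consistent_with_evaluator(self, grid14):
        cf = self.cf_from_values(grid14, [-1, 0, 0.5, 0.2, 0.9])
        assert np.allclose(cf.grid_values, cf(grid14.bin_centers))

    def test_pointwise_se_positive_for_nondegenerate_cov(self, grid14):
        cf = self.cf_from_values(grid14, [-1, 0, 0.5, 0.2, 0.9], se=0.3)
        assert np.all(cf.pointwise_se > 0)


def age_table(responses, ages, colonies=None, family="gaussian"):
    n = len(responses)
    df = pd.DataFrame({
        "unit_id": [f"u{i}" for i in range(n)],
        "colony_id": colonies if colonies is not None else ["c1"] * n,
        "response": responses,
        "week": ages,
    })
    return VitalRateTable("test_rate", family, df)


class TestAgeModel:
    def test_concave_quadratic_labelled_concave(self):
        rng = np.random.default_rng(21)
        ages = np.tile(np.arange(7.0, 85.0, 7.0), 8)
        cols = np.repeat([f"c{i}" for i in range(8)], 12)
        y = -0.01 * (ages - 45) ** 2 + rng.normal(0, 1.0, len(ages))
        fit = fit_age_model(age_table(y, ages, cols), ages)
        assert age_shape_label(fit) == "Concave"

    def test_constant_response_labelled_constant(self):
        rng = np.random.default_rng(22)
        ages = np.tile(np.arange(7.0, 85.0, 7.0), 8)
        cols = np.repeat([f"c{i}" for i in range(8)], 12)
        y = rng.normal(0, 1.0, len(ages))
        fit = fit_age_model(age_table(y, ages, cols), ages)
        assert age_shape_label(fit) == "Constant"
        assert not (fit.smooth_pvalue < 0.01)

    def test_decreasing_line_labelled_decreases(self):
        rng = np.random.default_rng(23)
        ages = np.tile(np.arange(7.0, 85.0, 7.0), 8)
        cols = np.repeat([f"c{i}" for i in range(8)], 12)
        y = -0.05 * ages + rng.normal(0, 0.5, len(ages))
        fit = fit_age_model(age_table(y, ages, cols), ages)
        assert age_shape_label(fit) == "Decreases"

    def test_nonpositive_ages_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_age_model(age_table([1.0, 2.0], [0.0, 7.0]), [0.0, 7.0])
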