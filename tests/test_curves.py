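"""Spline smoothing, GCV, AUC timing, shape clustering, GO timing tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from phytotime import curves as cv


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestSmoother:
    def test_linear_data_reproduced_under_any_penalty(self):
        t = np.linspace(0, 1, 25)
        y = 2.0 * t - 0.3
        for lam in (0.0, 1e-3, 1.0, 100.0):
            sm = cv.PenalizedBSplineSmoother(n_basis=12, lam=lam).fit(t, y)
            assert np.abs(sm.predict(t) - y).max() <= 1e-8

    def test_unpenalized_saturated_fit_interpolates(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 10)
        y = rng.normal(size=10)
        sm = cv.PenalizedBSplineSmoother(n_basis=10, lam=0.0).fit(t, y)
        assert sm.rss_ <= 1e-16

    def test_gcv_minimizer_matches_loo_oracle(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 1, 40)
        y = sigmoid((t - 0.5) / 0.08) + rng.normal(0, 0.1, size=40)
        lambdas = np.logspace(-6, 2, 9)
        gcvs, loos = [], []
        for lam in lambdas:
            sm = cv.PenalizedBSplineSmoother(n_basis=12, lam=lam).fit(t, y)
            H = sm.hat_matrix(t)
            resid = y - sm.predict(t)
            loos.append(np.mean((resid / (1 - np.diag(H))) ** 2))
            gcvs.append(sm.gcv_)
        assert int(np.argmin(gcvs)) == int(np.argmin(loos))

    def test_gcv_equals_loo_shortcut_form(self):
        # for a linear smoother GCV replaces each h_ii by tr(H)/n
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 30)
        y = rng.normal(size=30)
        sm = cv.PenalizedBSplineSmoother(n_basis=8, lam=0.5).fit(t, y)
        H = sm.hat_matrix(t)
        n = len(t)
        resid = y - H @ y
        gcv_manual = n * (resid @ resid) / (n - np.trace(H)) ** 2
        assert sm.gcv_ == pytest.approx(gcv_manual, rel=1e-10)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            cv.PenalizedBSplineSmoother().fit([0.5, 0.2, 0.9], [1, 2, 3])


class TestHyperparameterSelection:
    def _matrix(self, seed=0, n_genes=30, smooth=True):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 40)
        rowsfn = (
            (lambda: sigmoid((t - rng.uniform(0.2, 0.8)) / 0.1) + rng.normal(0, 0.05, 40))
            if smooth
            else (lambda: rng.normal(size=40))
        )
        Y = pd.DataFrame([rowsfn() for _ in range(n_genes)],
                         index=[f"g{i}" for i in range(n_genes)])
        return Y, t

    def test_one_point_grid_returned(self):
        Y, t = self._matrix()
        nb, lam, surface = cv.select_hyperparameters(Y, t, basis_grid=[10], lambda_grid=[0.1])
        assert (nb, lam) == (10, 0.1) and len(surface) == 1

    def test_argmin_contract(self):
        Y, t = self._matrix()
        nb, lam, surface = cv.select_hyperparameters(
            Y, t, basis_grid=[12], lambda_grid=[1e-4, 1e2]
        )
        best = surface.loc[surface["total_gcv"].idxmin()]
        assert lam == best["lam"]

    def test_noise_demands_more_smoothing_than_trend(self):
        # pure-noise genes push GCV toward heavy smoothing; linear trends sit
        # in the penalty null space, so any lambda fits them equally well
        lambdas = list(np.logspace(-6, 2, 9))
        noisy, t = self._matrix(seed=3, smooth=False)
        trend = pd.DataFrame(np.outer(np.arange(1, 6), t), columns=noisy.columns)
        _, lam_noise, _ = cv.select_hyperparameters(noisy, t, basis_grid=[12], lambda_grid=lambdas)
        _, lam_trend, _ = cv.select_hyperparameters(trend, t, basis_grid=[12], lambda_grid=lambdas)
        assert lam_noise >= lam_trend

    def test_empty_grid_rejected(self):
        Y, t = self._matrix()
        with pytest.raises(ValueError):
            cv.select_hyperparameters(Y, t, basis_grid=[], lambda_grid=[0.1])


class TestGeneSelection:
    def test_identity_and_sorting(self):
        gcv = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3})
        assert list(cv.select_top_genes_by_gcv(gcv, k=3)) == ["a", "b", "c"]
        assert list(cv.select_top_genes_by_gcv(gcv, k=2)) == ["a", "b"]

    def test_tie_broken_by_gene_id(self):
        gcv = pd.Series({"z": 0.1, "a": 0.1, "m": 0.5})
        assert list(cv.select_top_genes_by_gcv(gcv, k=2)) == ["a", "z"]

    def test_noiseless_beats_noise_at_half(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 1, 40)
        clean = [sigmoid((t - s) / 0.1) for s in np.linspace(0.3, 0.7, 10)]
        noise = [rng.normal(size=40) for _ in range(10)]
        Y = pd.DataFrame(clean + noise,
                         index=[f"clean{i}" for i in range(10)] + [f"noise{i}" for i in range(10)])
        _, gcv, _ = cv._batch_fit(Y.to_numpy(), t, 12, 1.0)
        top = cv.select_top_genes_by_gcv(pd.Series(gcv, index=Y.index), k=10)
        assert all(g.startswith("clean") for g in top)

    def test_bad_k(self):
        with pytest.raises(ValueError):
            cv.select_top_genes_by_gcv(pd.Series({"a": 1.0}), k=0)


class TestRangeIqrFilter:
    def test_spike_gene_dropped(self):
        vals = pd.DataFrame([[0.0] * 9 + [10.0]], index=["g"])
        assert not cv.range_iqr_filter(vals)["g"]

    def test_uniform_ramp_kept(self):
        # range 1, IQR 0.5 -> ratio 2 at default threshold 4
        ramp = pd.DataFrame([np.linspace(0, 1, 68)], index=["g"])
        assert cv.range_iqr_filter(ramp)["g"]

    def test_constant_gene_dropped(self):
        vals = pd.DataFrame([[1.0] * 10], index=["g"])
        assert not cv.range_iqr_filter(vals)["g"]


def _fit(yfunc, n=101, n_basis=20, lam=1e-8):
    t = np.linspace(0, 1, n)
    return cv.fit_penalized_spline(yfunc(t), t, n_basis=n_basis, lam=lam)


class TestMonotonicityAndAUC:
    def test_linear_increasing(self):
        fit = _fit(lambda t: t)
        mono, direction = cv.monotonicity_flag(fit)
        assert mono and direction == "increasing"

    def test_sine_not_monotone(self):
        fit = _fit(lambda t: np.sin(2 * np.pi * t))
        mono, _ = cv.monotonicity_flag(fit)
        assert not mono

    def test_shallow_dip_within_tolerance_is_monotone(self):
        # hand-built spline whose middle section dips by 1e-5: the derivative
        # genuinely crosses zero, but stays inside the +/-1e-3 tolerance band
        from scipy.interpolate import BSpline

        from phytotime.curves import SplineFit, _knots, PenalizedBSplineSmoother

        coef = np.array([0.0, 0.2, 0.5, 0.5 + 1e-5, 0.5 - 1e-5, 0.5, 0.8, 1.0])
        sm = PenalizedBSplineSmoother(n_basis=8, lam=0.0)
        sm.knots_ = _knots(8)
        sm.coef_ = coef
        sm.spline_ = BSpline(sm.knots_, coef, 3)
        grid_vals = sm.spline_(cv.EVAL_GRID)
        fit = SplineFit("dip", sm, float(grid_vals.min()), float(grid_vals.max()), 0.0)
        raw_d = fit.derivative(cv.EVAL_GRID)
        assert (raw_d < 0).any()  # the dip is real
        mono, direction = cv.monotonicity_flag(fit, tol=1e-3)
        assert mono and direction == "increasing"
        mono_strict, _ = cv.monotonicity_flag(fit, tol=0.0)
        assert not mono_strict

    def test_auc_of_descending_line_is_half(self):
        fit = _fit(lambda t: 1 - t)
        assert cv.auc_timing(fit, "decreasing") == pytest.approx(0.5, abs=1e-6)

    def test_auc_of_ascending_line_is_half_by_symmetry(self):
        fit = _fit(lambda t: t)
        assert cv.auc_timing(fit, "increasing") == pytest.approx(0.5, abs=1e-6)

    def test_auc_matches_symbolic_logistic_integral(self):
        import sympy

        ts = sympy.symbols("t")
        for t0, w, decreasing in [(0.3, 0.08, False), (0.6, 0.15, False),
                                  (0.5, 0.05, True), (0.25, 0.06, True)]:
            expr = 1 / (1 + sympy.exp(-(ts - t0) / w))
            if decreasing:
                expr = 1 - expr
            integral = float(sympy.integrate(expr, (ts, 0, 1)))
            f0, f1 = float(expr.subs(ts, 0)), float(expr.subs(ts, 1))
            lo, hi = min(f0, f1), max(f0, f1)
            rescaled_integral = (integral - lo) / (hi - lo)
            expected = rescaled_integral if decreasing else 1.0 - rescaled_integral
            sign = -1.0 if decreasing else 1.0
            fit = _fit(lambda t: (1 - sigmoid((t - t0) / w)) if sign < 0
                       else sigmoid((t - t0) / w), n=301, n_basis=24, lam=1e-10)
            direction = "decreasing" if decreasing else "increasing"
            assert cv.auc_timing(fit, direction) == pytest.approx(expected, abs=1e-4)

    def test_non_monotone_auc_rejected(self):
        fit = _fit(lambda t: np.sin(2 * np.pi * t))
        with pytest.raises(ValueError):
            cv.auc_timing(fit, "increasing")

    def test_endpoint_rule_consistent_with_derivative_direction(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t0 = rng.uniform(0.2, 0.8)
            w = rng.uniform(0.05, 0.2)
            sgn = rng.choice([-1, 1])
            fit = _fit(lambda t: sigmoid(sgn * (t - t0) / w), n_basis=16, lam=1e-6)
            mono, direction = cv.monotonicity_flag(fit)
            assert mono
            vals = fit(np.array([0.0, 1.0]))
            endpoint_dir = "decreasing" if vals[0] > vals[1] else "increasing"
            assert direction == endpoint_dir


class TestShapeDistance:
    def test_identity_and_scaling(self):
        x = np.array([0.0, 0.4, 1.0, 0.5, 0.1])
        assert cv.shape_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert cv.shape_distance(x, 3 * x) == pytest.approx(0.0, abs=1e-12)

    def test_shift_closer_than_random(self):
        rng = np.random.default_rng(6)
        x = sigmoid((np.linspace(0, 1, 30) - 0.5) / 0.05)
        shifted = np.roll(x, 2)
        shifted[:2] = 0.0
        unrelated = rng.normal(size=30)
        assert cv.shape_distance(x, shifted) < cv.shape_distance(x, unrelated)

    def test_brute_force_lag_search(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=12), rng.normal(size=12)
        best = -np.inf
        for lag in range(-11, 12):
            z = np.zeros(12)
            if lag >= 0:
                z[lag:] = y[: 12 - lag]
            else:
                z[:lag] = y[-lag:]
            best = max(best, x @ z)
        expected = 1 - best / (np.linalg.norm(x) * np.linalg.norm(y))
        assert cv.shape_distance(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cv.shape_distance(np.zeros(5), np.ones(5))


class TestKShape:
    def _families(self, n_per=15, length=40, seed=8):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, length)
        fam_a = [sigmoid((t - 0.3) / 0.05) + rng.normal(0, 0.02, length) for _ in range(n_per)]
        fam_b = [1 - sigmoid((t - 0.7) / 0.05) + rng.normal(0, 0.02, length) for _ in range(n_per)]
        X = np.array(fam_a + fam_b)
        truth = np.array([0] * n_per + [1] * n_per)
        return X, truth

    def test_identical_curves_have_zero_wss(self):
        X = np.tile(np.linspace(0.1, 1, 20), (6, 1))
        km = cv.KShapeClusterer(n_clusters=2, random_state=0).fit(X)
        assert km.wss_ == pytest.approx(0.0, abs=1e-10)

    def test_two_shape_families_recovered(self):
        X, truth = self._families()
        km = cv.KShapeClusterer(n_clusters=2, random_state=0).fit(X)
        agree = max((km.labels_ == truth).mean(), (km.labels_ != truth).mean())
        assert agree == 1.0

    def test_wss_non_increasing_in_k(self):
        X, _ = self._families()
        _, wss, _ = cv.wss_elbow(X, k_range=range(2, 7), n_restarts=5, random_state=0)
        diffs = np.diff(wss.to_numpy())
        assert (diffs <= 1e-8).all()

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            cv.KShapeClusterer(n_clusters=5).fit(np.ones((3, 10)))


class TestGoTimingTests:
    def _run(self, groups):
        timing = pd.DataFrame(
            {
                "monotone": True,
                "direction": "decreasing",
                "auc": np.concatenate(list(groups.values())),
            },
            index=[f"g{i}" for i in range(sum(map(len, groups.values())))],
        )
        rows = []
        i = 0
        for term, vals in groups.items():
            for _ in vals:
                rows.append({"gene_id": f"g{i}", "term_id": term})
                i += 1
        go_map = pd.DataFrame(rows)
        return cv.go_group_auc_tests(timing, go_map, size_bounds=(2, 1000))

    def test_null_omnibus_calibrated(self):
        rng = np.random.default_rng(9)
        n_reps, hits = 400, 0
        from scipy.stats import kruskal

        for _ in range(n_reps):
            groups = [rng.uniform(size=15) for _ in range(3)]
            _, p = kruskal(*groups)
            hits += p < 0.01
        se = np.sqrt(0.01 * 0.99 / n_reps)
        assert hits / n_reps < 0.01 + 3 * se

    def test_shifted_term_separated_in_letters(self):
        rng = np.random.default_rng(10)
        n_sims, separated = 60, 0
        for _ in range(n_sims):
            groups = {
                "base1": rng.uniform(0, 0.4, 30),
                "base2": rng.uniform(0, 0.4, 30),
                "shifted": rng.uniform(0.3, 0.7, 30),
            }
            res = self._run(groups)
            letters = res["letters"]
            if not (set(letters["shifted"]) & (set(letters["base1"]) | set(letters["base2"]))):
                separated += 1
        assert separated / n_sims >= 0.95

    def test_identical_groups_not_separated(self):
        vals = np.linspace(0.1, 0.9, 20)
        res = self._run({"a": vals, "b": vals.copy()})
        assert res["pairwise_p"].loc["a", "b"] > 0.9
        assert set(res["letters"]["a"]) & set(res["letters"]["b"])

    def test_too_few_terms_rejected(self):
        with pytest.raises(ValueError):
            self._run({"only": np.arange(5.0)})


def test_noiseless_auc_orders_switch_times(noiseless_pop, noiseless_pseudotime):
    from phytotime.pseudotime import normalize_for_pseudotime

    cp, de, _ = noiseless_pseudotime
    norm, _ = normalize_for_pseudotime(noiseless_pop.expression, de, flip_down=False)
    order = cp.consensus_rank_.sort_values().index
    Y = norm.loc[:, order]
    pos = np.linspace(0, 1, len(order))
    fits, _ = cv.fit_gene_curves(Y, pos, n_basis=12, lam=1.0)
    timing = cv.timing_table(fits)
    truth = noiseless_pop.truth.genes
    dec = timing[(truth.loc[timing.index, "direction"] == "decreasing") & timing["monotone"]]
    rho = spearmanr(dec["auc"], truth.loc[dec.index, "switch_time"]).statistic
    assert rho >= 0.95
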