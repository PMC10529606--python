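import numpy as np
import pandas as pd
import pytest

from puptrack.mpmm import (ModelData, build_model_data, classify_gamma,
                           fit_mpmm, loo_cv, model_select, nll_mpmm,
                           osa_residuals, vif)
from puptrack.regularize import RegularTrack
from puptrack.selection import aicc
from puptrack.simulate import simulate_model_cohort


# --------------------------------------------------------------------------
# independent oracle: adaptive Gauss-Hermite marginal likelihood, written
# with plain loops against the model equations, sharing no code with the
# Laplace implementation


def _oracle_marginal_nll(md, beta, sigma_b, sx, sy, n_nodes=21):
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    total = 0.0
    for a in range(md.n_animals):
        rows = np.flatnonzero(md.animal_idx == a)

        def cond_ll(b):
            ll = 0.0
            for t in rows:
                eta = float(md.X[t] @ beta) + b
                g = 1.0 / (1.0 + np.exp(-eta))
                for ax, s in ((0, sx), (1, sy)):
                    r = md.d[t, ax] - g * md.p[t, ax]
                    ll += -0.5 * np.log(2 * np.pi * s**2) - r**2 / (2 * s**2)
            return ll

        # adapt the quadrature grid to the integrand's mode and curvature
        bs = np.linspace(-4 * sigma_b, 4 * sigma_b, 41)
        vals = [cond_ll(b) - b**2 / (2 * sigma_b**2) for b in bs]
        b_hat = bs[int(np.argmax(vals))]
        eps = max(1e-4, sigma_b / 50)
        curv = (cond_ll(b_hat + eps) - 2 * cond_ll(b_hat) + cond_ll(b_hat - eps)) \
            / eps**2 - 1.0 / sigma_b**2
        scale = 1.0 / np.sqrt(max(-curv, 1e-12))
        log_terms = []
        for z, w in zip(nodes, weights):
            b = b_hat + scale * z
            log_f = (cond_ll(b) - b**2 / (2 * sigma_b**2)
                     - 0.5 * np.log(2 * np.pi * sigma_b**2))
            log_terms.append(np.log(w) + z**2 / 2 + log_f)
        m = max(log_terms)
        total += m + np.log(sum(np.exp(t - m) for t in log_terms)) \
            + np.log(scale)
    return -total


def _tiny_md(seed=0, n_animals=2, n_steps=30, sigma_b=0.3):
    md, truth = simulate_model_cohort(n_animals=n_animals, n_steps=n_steps,
                                      sigma_b=sigma_b, seed=seed)
    return md.with_covariates(["week", "ln_depth"]), truth


class TestLikelihood:
    def test_laplace_matches_quadrature_oracle(self):
        # small instance (2 animals, 30 steps) evaluated at and around the
        # generating parameters, where the optimizer actually operates
        md, truth = _tiny_md(seed=3, sigma_b=0.2)
        beta0 = np.array([truth["beta"].get(n, 0.0) for n in md.colnames])
        rng = np.random.default_rng(0)
        for trial in range(5):
            beta = beta0 if trial == 0 else beta0 * (
                1 + rng.uniform(-0.1, 0.1, beta0.size))
            for sigma_b in (0.1, 0.2, 0.3):
                ours = nll_mpmm(md, beta, np.log(sigma_b), np.log([4.0, 4.0]))
                oracle = _oracle_marginal_nll(md, beta, sigma_b, 4.0, 4.0)
                assert ours == pytest.approx(oracle, abs=1e-3)

    def test_sigma_b_to_zero_limit_is_conditional_likelihood(self):
        md, _ = _tiny_md(seed=4)
        beta = np.array([0.8, 0.0, 0.05])
        marginal = nll_mpmm(md, beta, np.log(1e-8), np.log([4.0, 4.0]))
        conditional = nll_mpmm(md, beta, None, np.log([4.0, 4.0]))
        assert marginal == pytest.approx(conditional, abs=1e-6 * md.n_steps)

    def test_nonfinite_parameters_rejected(self):
        md, _ = _tiny_md(seed=5)
        with pytest.raises(ValueError):
            nll_mpmm(md, np.array([np.nan, 0, 0]), 0.0, np.log([4.0, 4.0]))

    def test_truth_near_likelihood_optimum(self):
        # nll at the generating parameters should beat most random
        # 10 % perturbations
        md, truth = simulate_model_cohort(n_animals=8, n_steps=150, seed=6)
        names = md.colnames
        beta = np.array([truth["beta"].get(n, 0.0) for n in names])
        base = nll_mpmm(md, beta, np.log(truth["sigma_b"]),
                        np.log(truth["sigma_step_km"]))
        rng = np.random.default_rng(7)
        worse = 0
        n_pert = 40
        for _ in range(n_pert):
            pert = beta * (1 + rng.uniform(-0.1, 0.1, beta.size))
            if nll_mpmm(md, pert, np.log(truth["sigma_b"]),
                        np.log(truth["sigma_step_km"])) >= base:
                worse += 1
        assert worse >= 0.8 * n_pert


class TestBuildModelData:
    def _track(self, animal, n, seed=0, pup=None):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "time": pd.date_range("2016-02-01", periods=n, freq="6h"),
            "lon": -58.3 + np.cumsum(rng.normal(0, 0.02, n)),
            "lat": 43.2 + np.cumsum(rng.normal(0, 0.02, n)),
            "depth_m": np.full(n, 100.0), "ln_depth": np.full(n, np.log(100.0)),
            "dist_shore_km": np.full(n, 50.0), "week": np.ones(n, dtype=int),
        })
        pup = pup or {"sex": "female", "mass": 55.0, "length": 111.0,
                      "postwean": 20.0}
        return RegularTrack(f"{animal}-K1", animal, 6.0, df, pup)

    def test_51_points_give_49_usable_steps(self):
        md = build_model_data([self._track("A", 51)], ["ln_depth"])
        assert md.n_steps == 49

    def test_two_animals_two_levels(self):
        md = build_model_data([self._track("A", 20, 1), self._track("B", 20, 2)],
                              ["ln_depth"])
        assert md.n_animals == 2
        assert set(md.animal_idx) == {0, 1}

    def test_missing_biometrics_excludes_animal(self):
        bad = self._track("B", 20, 2, pup={"sex": "female", "mass": np.nan,
                                           "length": 111.0, "postwean": 20.0})
        md = build_model_data([self._track("A", 20, 1), bad],
                              ["mass", "ln_depth"])
        assert md.animal_ids == ["A"]


class TestFit:
    def test_straight_line_track_gives_gamma_near_one(self):
        n = 120
        df = pd.DataFrame({
            "time": pd.date_range("2016-02-01", periods=n, freq="6h"),
            "lon": -58.3 + 0.05 * np.arange(n),
            "lat": 43.2 + 0.02 * np.arange(n),
        })
        rt = RegularTrack("A-K1", "A", 6.0, df, {})
        fit = fit_mpmm(build_model_data([rt], []), [], random_intercept=False)
        assert np.all(fit.gamma > 0.99)
        assert fit.beta.loc["intercept", "estimate"] > 3.0

    def test_white_noise_displacements_give_low_gamma(self):
        rng = np.random.default_rng(8)
        n = 400
        d = rng.normal(0, 4, (n, 2))
        md = ModelData(d=d[1:], p=d[:-1], X=np.ones((n - 1, 1)),
                       colnames=["intercept"], animal_idx=np.zeros(n - 1, int),
                       animal_ids=["A"], track_idx=np.zeros(n - 1, int))
        fit = fit_mpmm(md, [], random_intercept=False)
        assert float(np.mean(fit.gamma)) < 0.1

    def test_recovers_generating_parameters(self):
        md, truth = simulate_model_cohort(n_animals=12, n_steps=200, seed=9)
        fit = fit_mpmm(md)
        names = md.colnames
        tv = np.array([truth["beta"].get(n, 0.0) for n in names])
        est = fit.beta["estimate"].to_numpy()
        # strongly identified step-level covariates recover their signs
        for cov in ("week", "dist_shore", "ln_depth"):
            j = names.index(cov)
            assert np.sign(est[j]) == np.sign(tv[j])
        assert fit.sigma_step[0] == pytest.approx(4.0, rel=0.1)
        assert np.all((fit.gamma > 0) & (fit.gamma < 1))


class TestDiagnostics:
    def test_classify_thresholds(self):
        labels, counts = classify_gamma(np.array([0.71, 0.70, 0.30, 0.29, 0.5]))
        assert list(labels) == ["directed_travel", "intermediate", "intermediate",
                                "area_restricted_search", "intermediate"]
        assert counts == {"directed_travel": 1, "intermediate": 3,
                          "area_restricted_search": 1}

    def test_classify_counts_match_brute_force(self):
        rng = np.random.default_rng(10)
        g = rng.uniform(0.01, 0.99, 500)
        _, counts = classify_gamma(g)
        assert counts["directed_travel"] == int(sum(1 for v in g if v > 0.70))
        assert counts["area_restricted_search"] == int(sum(1 for v in g if v < 0.30))

    def test_osa_residuals_white_under_truth(self):
        md, truth = simulate_model_cohort(n_animals=6, n_steps=300, seed=11)
        fit = fit_mpmm(md)
        res = osa_residuals(fit)
        n = md.n_steps
        for ax in ("x", "y"):
            acf1 = pd.Series(res[ax]).autocorr(1)
            assert abs(acf1) < 3 / np.sqrt(n)
            assert abs(np.mean(res[ax])) < 3 / np.sqrt(n)

    def test_misspecified_zero_gamma_leaves_autocorrelation(self):
        md, _ = simulate_model_cohort(n_animals=4, n_steps=300, seed=12)
        fit = fit_mpmm(md.with_covariates([]), [], random_intercept=False)
        fit.gamma = np.zeros_like(fit.gamma)  # force the no-persistence forecast
        res = osa_residuals(fit)
        assert pd.Series(res["x"]).autocorr(1) > 0.3


class TestSelectionAndCv:
    def test_aicc_identity_from_published_row(self):
        assert aicc(17376.96, 6, 5826) == pytest.approx(-34741.90, abs=0.01)
        assert aicc(17473.49, 13, 5826) == pytest.approx(-34920.91, abs=0.01)

    def test_aicc_tends_to_aic(self):
        ll, k = -100.0, 5
        assert aicc(ll, k, 10**9) == pytest.approx(-2 * ll + 2 * k, abs=1e-3)

    def test_model_select_ranks_and_weights(self):
        md, _ = simulate_model_cohort(n_animals=6, n_steps=120, seed=13)
        table, fits = model_select(md, [["week", "ln_depth"], []])
        assert table["weight"].sum() == pytest.approx(1.0)
        assert (table["dAICc"] >= 0).all()
        assert table["dAICc"].iloc[0] == 0.0

    def test_vif_closed_forms(self):
        n = 4000
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, n)
        b_ = rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), a, b_])
        md = ModelData(d=np.zeros((n, 2)), p=np.zeros((n, 2)), X=X,
                       colnames=["intercept", "a", "b"],
                       animal_idx=np.zeros(n, int), animal_ids=["A"],
                       track_idx=np.zeros(n, int))
        v = vif(md, ["a", "b"])
        assert v["a"] == pytest.approx(1.0, abs=0.01)
        # exact correlation 0.6 -> VIF = 1/(1-0.36) = 1.5625
        a_std = (a - a.mean()) / a.std()
        b_std = (b_ - b_.mean()) / b_.std()
        b_orth = b_std - (a_std @ b_std / n) * a_std
        b_orth /= b_orth.std()
        c = 0.6 * a_std + np.sqrt(1 - 0.36) * b_orth
        X2 = np.column_stack([np.ones(n), a_std, c])
        md2 = ModelData(d=np.zeros((n, 2)), p=np.zeros((n, 2)), X=X2,
                        colnames=["intercept", "a", "c"],
                        animal_idx=np.zeros(n, int), animal_ids=["A"],
                        track_idx=np.zeros(n, int))
        v2 = vif(md2, ["a", "c"])
        assert v2["a"] == pytest.approx(1.5625, abs=1e-9)

    def test_vif_duplicate_is_infinite(self):
        n = 100
        x = np.random.default_rng(15).normal(0, 1, n)
        X = np.column_stack([np.ones(n), x, x])
        md = ModelData(d=np.zeros((n, 2)), p=np.zeros((n, 2)), X=X,
                       colnames=["intercept", "x", "x2"],
                       animal_idx=np.zeros(n, int), animal_ids=["A"],
                       track_idx=np.zeros(n, int))
        assert np.isinf(vif(md, ["x", "x2"]).max())

    def test_loo_refits_every_animal_and_brackets_stable_fit(self):
        md, _ = simulate_model_cohort(n_animals=5, n_steps=120, sigma_b=0.0,
                                      seed=16)
        full = fit_mpmm(md, ["week", "ln_depth"])
        cv = loo_cv(md, full_fit=full)
        assert cv.n_attempted == 5
        assert cv.n_converged == 5
        # homogeneous animals: refits stay inside the full model's 95% CI
        assert (cv.est_trend >= 80.0).all()
        est = full.beta["estimate"]
        assert (cv.coef_quantiles["q05"] <= est + 1e-9).all()
        assert (cv.coef_quantiles["q95"] >= est - 1e-9).all()

    def test_loo_needs_three_animals(self):
        md, _ = simulate_model_cohort(n_animals=2, n_steps=60, seed=17)
        with pytest.raises(ValueError):
            loo_cv(md, ["week"])
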