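"""Spearman screen, VIF exclusion, and Gamma log-link mixed models."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from cartwheel.inference import (
    ModelSpec,
    fit_gamma_glmm,
    run_female_choice_analysis,
    run_group_size_analysis,
    spearman_matrix,
    vif_screen,
)
from cartwheel.synthgen import CourtSimParams, simulate_court_dataset


class TestSpearman:
    def test_self_correlation_is_one_and_negation_minus_one(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": -x})
        corr = spearman_matrix(df)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_known_rank_dependence_recovered(self, rng):
        """Gaussian copula with rank correlation ~0.8 at n=500."""
        target_rho = 0.8
        # invert the bivariate-normal relation rho_s = (6/pi) asin(r/2)
        r = 2 * np.sin(np.pi * target_rho / 6)
        cov = [[1, r], [r, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=500)
        df = pd.DataFrame({"x": xy[:, 0], "y": np.exp(xy[:, 1])})  # monotone warp
        corr = spearman_matrix(df)
        assert corr.loc["x", "y"] == pytest.approx(target_rho, abs=0.05)

    def test_constant_column_flagged_undefined(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            corr = spearman_matrix(df)
        assert np.isnan(corr.loc["a", "b"])

    def test_heatmap_export(self, rng, tmp_path):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["rr", "det", "lam"])
        out = tmp_path / "corr.png"
        spearman_matrix(df, heatmap_path=out)
        assert out.stat().st_size > 0


class TestVIF:
    def test_orthogonal_predictors_all_one_none_dropped(self):
        n = 40
        t = np.arange(n)
        df = pd.DataFrame(
            {
                "a": np.sin(2 * np.pi * t / n),
                "b": np.cos(2 * np.pi * t / n),
                "c": np.sin(4 * np.pi * t / n),
            }
        )
        report = vif_screen(df)
        assert report.dropped == []
        assert all(v == pytest.approx(1.0, abs=0.05) for v in report.final_vifs().values())

    def test_duplicate_column_flagged_infinite_and_dropped(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        report = vif_screen(df)
        assert len(report.dropped) == 1
        assert report.dropped[0] in ("a", "b")
        assert np.isinf(report.trace[0]["vif"][report.dropped[0]])

    def test_constructed_vif_20_predictor_dropped(self, rng):
        """x3 = linear combination + noise tuned to R^2 = 0.95 -> VIF = 20."""
        n = 2000
        x1, x2 = rng.normal(size=(2, n))
        signal = x1 + x2  # var 2
        noise = rng.normal(size=n)
        # scale noise for R^2 = 0.95: var(signal)/(var(signal)+var(noise)) = 0.95
        noise *= np.sqrt(np.var(signal) * 0.05 / 0.95 / np.var(noise))
        df = pd.DataFrame({"x1": x1, "x2": x2, "x3": signal + noise})
        report = vif_screen(df)
        assert report.trace[0]["vif"]["x3"] == pytest.approx(20.0, rel=0.15)
        assert "x3" in report.dropped
        assert set(report.retained) == {"x1", "x2"}

    def test_needs_two_predictors_and_enough_rows(self):
        with pytest.raises(ValueError):
            vif_screen(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            vif_screen(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestGammaGLMM:
    def test_wald_chi2_is_estimate_over_se_squared(self):
        df = simulate_court_dataset(CourtSimParams(n_courts=10, displays_per_court=8, seed=4))
        res = fit_gamma_glmm(
            df, ModelSpec(response="mcentr", predictors=("n_males",), standardize_predictors=False)
        )
        t = res.table()
        assert np.allclose(t["chi2"], (t["estimate"] / t["se"]) ** 2)

    def test_standardization_is_reparameterization_only(self):
        """Same maximized likelihood whether or not predictors are scaled."""
        df = simulate_court_dataset(CourtSimParams(n_courts=12, displays_per_court=8, seed=5))
        spec_raw = ModelSpec(
            response="visit_rate", predictors=("rr", "mcentr"), standardize_predictors=False
        )
        spec_std = ModelSpec(
            response="visit_rate", predictors=("rr", "mcentr"), standardize_predictors=True
        )
        raw = fit_gamma_glmm(df, spec_raw)
        std = fit_gamma_glmm(df, spec_std)
        assert raw.fit.loglik == pytest.approx(std.fit.loglik, abs=1e-3)
        # slope on the standardized scale = raw slope * predictor sd
        sd_rr = df["rr"].std(ddof=0)
        assert std.fit.coef[1] == pytest.approx(raw.fit.coef[1] * sd_rr, rel=1e-2)

    def test_slope_recovery_short(self):
        """Mini recovery run; the full experiment lives in the acceptance suite."""
        est = []
        for seed in range(10):
            df = simulate_court_dataset(
                CourtSimParams(n_courts=30, displays_per_court=10, seed=300 + seed)
            )
            r = fit_gamma_glmm(
                df,
                ModelSpec(response="mcentr", predictors=("n_males",), standardize_predictors=False),
            )
            est.append(r.fit.coef[1])
        assert np.mean(est) == pytest.approx(0.04, abs=0.015)

    def test_zero_group_variance_estimated_near_zero(self):
        hits = 0
        for seed in range(10):
            df = simulate_court_dataset(
                CourtSimParams(n_courts=20, displays_per_court=10, court_sd=0.0, seed=600 + seed)
            )
            r = fit_gamma_glmm(
                df,
                ModelSpec(response="mcentr", predictors=("n_males",), standardize_predictors=False),
            )
            hits += r.fit.ranef_var <= 0.01
        assert hits >= 9

    def test_single_court_falls_back_to_glm(self):
        df = simulate_court_dataset(CourtSimParams(n_courts=1, displays_per_court=30, seed=6))
        with pytest.warns(UserWarning, match="falling back"):
            r = fit_gamma_glmm(
                df,
                ModelSpec(response="mcentr", predictors=("n_males",), standardize_predictors=False),
            )
        assert r.fit.method == "glm"
        assert r.fit.singular

    def test_zero_responses_shifted_and_logged(self):
        df = simulate_court_dataset(CourtSimParams(n_courts=10, displays_per_court=10, seed=7))
        assert (df["copulation_rate"] == 0).any()  # zeros are the norm here
        r = fit_gamma_glmm(
            df, ModelSpec(response="copulation_rate", predictors=("rr", "mcentr"))
        )
        assert r.zero_shift is not None
        smallest_pos = df.loc[df["copulation_rate"] > 0, "copulation_rate"].min()
        assert r.zero_shift == pytest.approx(smallest_pos / 2)

    def test_all_zero_response_is_clear_error(self):
        df = simulate_court_dataset(CourtSimParams(n_courts=5, displays_per_court=5, seed=8))
        df["copulation_rate"] = 0.0
        with pytest.raises(ValueError, match="zero everywhere"):
            fit_gamma_glmm(df, ModelSpec(response="copulation_rate", predictors=("rr",)))

    def test_likelihood_ratio_chi2_option(self):
        """LR single-term deletion gives a positive statistic that broadly
        agrees with Wald on well-behaved data."""
        df = simulate_court_dataset(CourtSimParams(n_courts=30, displays_per_court=10, seed=12))
        spec = ModelSpec(
            response="mcentr", predictors=("n_males",), standardize_predictors=False
        )
        wald = fit_gamma_glmm(df, spec)
        lr = fit_gamma_glmm(df, spec, chi2="lr")
        assert any("likelihood-ratio" in n for n in lr.notes)
        stat_w = wald.table().loc["n_males", "chi2"]
        stat_lr = lr.table().loc["n_males", "chi2"]
        assert stat_lr > 0
        assert stat_lr == pytest.approx(stat_w, rel=0.5)
        # estimates themselves are untouched by the test choice
        assert lr.table()["estimate"].equals(wald.table()["estimate"])

    def test_agrees_with_lme4_oracle(self, tmp_path):
        """Independent cross-check of the Laplace fit against R's glmer."""
        df = simulate_court_dataset(CourtSimParams(n_courts=30, displays_per_court=10, seed=42))
        res = fit_gamma_glmm(
            df, ModelSpec(response="mcentr", predictors=("n_males",), standardize_predictors=False)
        )
        csv = tmp_path / "courts.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            m <- glmer(mcentr ~ n_males + (1|court_id), data=d, family=Gamma(link='log'))
            co <- summary(m)$coefficients
            cat(co['n_males','Estimate'], co['n_males','Std. Error'], sep='\\n')
            """
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        slope_r, se_r = (float(v) for v in proc.stdout.strip().splitlines()[-2:])
        assert res.fit.coef[1] == pytest.approx(slope_r, abs=0.005)
        assert res.fit.se[1] == pytest.approx(se_r, rel=0.25)


class TestAnalyses:
    def test_group_size_analysis_fits_every_response(self):
        df = simulate_court_dataset(CourtSimParams(n_courts=10, displays_per_court=8, seed=9))
        results = run_group_size_analysis(df)
        assert set(results) == {"frequency", "rr", "det", "lam", "mcentr", "radius"}
        for res in results.values():
            assert "n_males" in res.table().index

    def test_entropy_effect_detected_others_not(self):
        """With only the entropy-group effect on, the mcentr model is the
        one that flags n_males."""
        detections = {k: 0 for k in ("frequency", "rr", "lam", "mcentr", "radius")}
        n_rep = 10
        for seed in range(n_rep):
            df = simulate_court_dataset(
                CourtSimParams(
                    n_courts=30, displays_per_court=10, beta_entropy_vs_males=0.06,
                    beta_rate_vs_rr=0.0, beta_rate_vs_entropy=0.0, beta_rate_vs_males=0.0,
                    seed=900 + seed,
                )
            )
            results = run_group_size_analysis(df, tuple(detections))
            for resp, res in results.items():
                detections[resp] += res.table().loc["n_males", "p"] < 0.05
        assert detections["mcentr"] >= 0.8 * n_rep
        for resp in ("frequency", "rr", "lam", "radius"):
            assert detections[resp] <= 0.3 * n_rep

    def test_female_choice_signs_recovered(self):
        """Positive RR effect and negative entropy effect on both rates."""
        sign_hits = 0
        n_rep = 10
        for seed in range(n_rep):
            df = simulate_court_dataset(
                CourtSimParams(
                    n_courts=30, displays_per_court=10,
                    beta_rate_vs_rr=0.25, beta_rate_vs_entropy=-0.25, seed=1500 + seed,
                )
            )
            visit, cop = run_female_choice_analysis(df)
            t = visit.table()
            sign_hits += (t.loc["rr", "estimate"] > 0) and (t.loc["mcentr", "estimate"] < 0)
        assert sign_hits >= 0.8 * n_rep

    def test_intercept_matches_log_mean_on_null_centered_data(self):
        df = simulate_court_dataset(
            CourtSimParams(
                n_courts=20, displays_per_court=10, court_sd=0.0,
                beta_rate_vs_rr=0.0, beta_rate_vs_entropy=0.0, beta_rate_vs_males=0.0,
                seed=10,
            )
        )
        visit, _ = run_female_choice_analysis(df)
        y = df["visit_rate"].to_numpy(dtype=float)
        shift = visit.zero_shift or 0.0
        y = np.where(y == 0, shift, y)
        assert visit.fit.coef[0] == pytest.approx(np.log(y.mean()), abs=0.1)

    def test_court_mean_aggregation_mode(self):
        df = simulate_court_dataset(CourtSimParams(n_courts=12, displays_per_court=6, seed=11))
        visit, cop = run_female_choice_analysis(df, aggregate="court_mean")
        assert visit.fit.n_obs == 12
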