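"""Repeatability, mixed-model machinery, and supporting statistics."""

import numpy as np
import pandas as pd
import pytest

from flightmaneuvers import stats
from flightmaneuvers.stats import (
    _aicc,
    _fit_intercept_only,
    _fit_lmm_ml,
    aspect_ratio,
    candidate_models,
    fit_and_select,
    grubbs_outliers,
    repeatability,
    residual_burst,
    trim_outliers,
)
from flightmaneuvers.synthetic import PopulationPlan, gen_population


class TestTrimOutliers:
    def test_single_extreme_value_removed(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(size=1000), [8.0]])
        kept, n = trim_outliers(x, 5.0)
        assert 8.0 not in kept
        assert n / len(x) <= 0.0031  # published removal fraction range

    def test_constant_sample_untouched(self):
        kept, n = trim_outliers(np.full(10, 2.0))
        assert n == 0 and len(kept) == 10

    def test_infinite_threshold_is_identity(self):
        x = np.array([0.0, 1.0, 100.0])
        kept, n = trim_outliers(x, np.inf)
        assert n == 0 and np.array_equal(kept, x)


class TestResidualBurst:
    @staticmethod
    def _traits(rng, slope=0.0, n=20):
        ar = rng.normal(7.7, 0.3, n)
        load = 6.0 + slope * (ar - 7.7) + rng.normal(0, 0.5, n)
        return pd.DataFrame(
            {
                "bird_id": [f"b{i}" for i in range(n)],
                "aspect_ratio": ar,
                "load_lifted": load,
                "experiment": ["CA1"] * (n // 2) + ["BC"] * (n - n // 2),
            }
        )

    def test_residuals_orthogonal_to_aspect_ratio(self):
        tr = self._traits(np.random.default_rng(1), slope=-0.5)
        r = residual_burst(tr)
        ar = tr["aspect_ratio"] - tr["aspect_ratio"].mean()
        assert abs(np.dot(r, ar)) < 1e-9

    def test_residuals_sum_to_zero_within_site(self):
        tr = self._traits(np.random.default_rng(2), slope=-0.5)
        tr = tr.assign(resid=residual_burst(tr))
        for _, sub in tr.groupby("experiment"):
            assert sub["resid"].sum() == pytest.approx(0.0, abs=1e-9)

    def test_collinear_load_gives_zero_residuals(self):
        tr = self._traits(np.random.default_rng(3))
        tr["load_lifted"] = 2.0 + 0.5 * tr["aspect_ratio"]
        assert np.max(np.abs(residual_burst(tr))) < 1e-9

    def test_too_few_birds(self):
        tr = self._traits(np.random.default_rng(4)).iloc[:2]  # 2 birds, 2 params
        with pytest.raises(ValueError):
            residual_burst(tr)


class TestAspectRatio:
    def test_published_morphology(self):
        # mean wing length and area from the study population
        assert aspect_ratio(50.97, 1355.0) == pytest.approx(7.67, abs=0.01)

    def test_scaling_law(self):
        # AR = 4 L^2 / S doubles when both length and area double
        assert aspect_ratio(2 * 50.0, 2 * 1355.0) == pytest.approx(2 * aspect_ratio(50.0, 1355.0))

    def test_unit_case(self):
        assert aspect_ratio(1.0, 4.0) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            aspect_ratio(-1.0, 10.0)


class TestCandidateModels:
    def test_days_effect_only_for_listed_metrics(self):
        vel = candidate_models("Vel_max")
        assert len(vel) == 8
        assert sum("days_post_capture" in m["predictors"] for m in vel) == 7
        pitch = candidate_models("PitchU_vel_avg")
        assert len(pitch) == 8
        assert all("days_post_capture" not in m["predictors"] for m in pitch)

    def test_null_model_is_intercept_only(self):
        assert candidate_models("Yaw_vel_avg")[-1] == {
            "name": "intercept-only",
            "predictors": [],
        }

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            candidate_models("NotAMetric")


def test_aicc_closed_form():
    # logLik = -10, k = 3, n = 52: AIC = 26, AICc = 26 + 24/48 = 26.5
    assert _aicc(-10.0, 3, 52) == pytest.approx(26.5)


class TestMixedModelFits:
    def test_intercept_only_matches_statsmodels_reml(self):
        """Dual-route check of the profiled REML fit against a general
        mixed-model optimizer on a well-conditioned dataset."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        rec, _, _ = gen_population(PopulationPlan(icc=0.7, metrics=("Vel_max",)), seed=3)
        y = rec["Vel_max"].to_numpy()
        g = rec["bird_id"].to_numpy()
        mu, s2b, s2e, _ = _fit_intercept_only(y, g)
        res = MixedLM(y, np.ones((len(y), 1)), groups=g).fit(reml=True)
        assert mu == pytest.approx(float(res.fe_params[0]), abs=1e-4)
        assert s2b == pytest.approx(float(np.asarray(res.cov_re)[0, 0]), abs=1e-4)
        assert s2e == pytest.approx(float(res.scale), abs=1e-4)

    def test_ml_fit_matches_statsmodels(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        plan = PopulationPlan(icc=0.6, metrics=("Vel_max",), betas={"Vel_max": {"burst": 0.5}})
        rec, traits, _ = gen_population(plan, seed=11)
        data = rec.merge(traits[["bird_id", "residual_burst"]], on="bird_id")
        y = data["Vel_max"].to_numpy()
        X = np.column_stack([np.ones(len(data)), data["competitor"], data["residual_burst"]])
        fit = _fit_lmm_ml(y, X, data["bird_id"].to_numpy())
        res = MixedLM(y, X, groups=data["bird_id"].to_numpy()).fit(reml=False)
        assert np.allclose(fit.fe_params, np.asarray(res.fe_params), atol=1e-4)
        assert fit.llf == pytest.approx(float(res.llf), abs=1e-4)

    def test_constant_response_degenerates_gracefully(self):
        y = np.full(10, 3.0)
        g = np.repeat(["a", "b"], 5)
        mu, s2b, s2e, conv = _fit_intercept_only(y, g)
        assert mu == 3.0 and s2b == 0.0 and s2e == 0.0 and conv


class TestRepeatability:
    def test_generative_recovery_at_true_icc_075(self):
        # sigma2_among = 3, sigma2_resid = 1: true ICC = 0.75
        rng = np.random.default_rng(10)
        ests = []
        for _ in range(200):
            b = rng.normal(0, np.sqrt(3.0), 20)
            rows = []
            for i in range(20):
                for j in range(rng.integers(2, 4)):
                    rows.append({"bird_id": f"b{i:02d}", "y": 5 + b[i] + rng.normal(0, 1.0)})
            df = pd.DataFrame(rows)
            ests.append(repeatability(df, "y", n_boot=0, seed=rng).icc)
        assert np.mean(ests) == pytest.approx(0.75, abs=0.05)

    def test_null_variance_classified_not_repeatable(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {"bird_id": np.repeat([f"b{i}" for i in range(20)], 3), "y": rng.normal(size=60)}
        )
        est = repeatability(df, "y", n_boot=200, seed=5)
        assert est.icc < 0.15
        assert est.classification == "not repeatable"

    def test_single_record_per_bird_rejected(self):
        df = pd.DataFrame({"bird_id": [f"b{i}" for i in range(10)], "y": np.arange(10.0)})
        with pytest.raises(ValueError):
            repeatability(df, "y", n_boot=10)

    def test_ci_brackets_point_estimate(self):
        rec, _, _ = gen_population(PopulationPlan(icc=0.8, metrics=("Vel_max",)), seed=8)
        est = repeatability(rec, "Vel_max", n_boot=300, seed=9)
        assert est.ci_low <= est.icc <= est.ci_high
        assert est.classification in {"high", "moderate"}


class TestModelSelection:
    def test_weights_sum_to_one_and_best_delta_zero(self):
        rec, traits, _ = gen_population(PopulationPlan(icc=0.6, metrics=("Vel_max",)), seed=21)
        s = fit_and_select(rec, traits, "Vel_max")
        assert s.table["weight"].sum() == pytest.approx(1.0)
        assert s.table["delta_AICc"].min() == 0.0
        assert 0.0 <= s.r2_marginal <= 1.0
        for imp in s.relative_importance.values():
            assert 0.0 <= imp <= 1.0 + 1e-12

    def test_single_supported_model_averaging_is_identity(self):
        """When one model dominates, the averaged coefficient must equal
        that model's own coefficient."""
        plan = PopulationPlan(
            icc=0.5,
            among_sd={"Vel_max": 0.1},
            metrics=("Vel_max",),
            betas={"Vel_max": {"burst": 1.2}},
        )
        rec, traits, _ = gen_population(plan, seed=30)
        s = fit_and_select(rec, traits, "Vel_max")
        if len(s.support) == 1:
            holder = s.support[0]
            assert "burst" in holder
        # regardless of support size, averaging preserves the sign here
        assert s.coefficients["burst"]["estimate"] > 0

    def test_burst_effect_recovery(self):
        hits = 0
        for rep in range(20):
            plan = PopulationPlan(
                icc=0.5,
                among_sd={"Vel_max": 0.15},
                metrics=("Vel_max",),
                betas={"Vel_max": {"burst": 0.8}},
            )
            rec, traits, _ = gen_population(plan, seed=600 + rep)
            s = fit_and_select(rec, traits, "Vel_max")
            ok = (
                s.relative_importance.get("burst", 0.0) > 0.9
                and s.coefficients.get("burst", {}).get("estimate", 0.0) > 0
            )
            hits += ok
        assert hits >= 18


class TestGrubbs:
    def test_arithmetic_example(self):
        # {1,1,1,10}: mean 3.25, sample SD 4.5, G = 6.75/4.5 = 1.5
        flags, gs = grubbs_outliers(np.array([1.0, 1.0, 1.0, 10.0]))
        dev = np.abs(np.array([1.0, 1.0, 1.0, 10.0]) - 3.25)
        assert dev.max() / np.array([1, 1, 1, 10.0]).std(ddof=1) == pytest.approx(1.5)
        # n = 4 gives a critical value close to 1.48: the 10 is flagged
        assert flags[3]

    def test_extreme_value_in_normal_sample_flagged(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(size=50), [6.0]])
        flags, gs = grubbs_outliers(x)
        assert flags[-1]
        assert all(g > 3.0 for g in gs[:1])

    def test_clean_samples_rarely_flagged(self):
        rng = np.random.default_rng(13)
        n_flagged = sum(
            grubbs_outliers(rng.normal(size=52))[0].any() for _ in range(40)
        )
        assert n_flagged <= 6  # ~5% type-I error rate

    def test_constant_sample_no_outliers(self):
        flags, gs = grubbs_outliers(np.full(5, 1.0))
        assert not flags.any() and gs == []
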