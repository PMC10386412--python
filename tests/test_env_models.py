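import numpy as np
import pandas as pd
import pytest

from phyloendemism import env_models as em
from phyloendemism.core_data import DataError, MetricSurface


def cells_index(n):
    return pd.Index([f"c{i:04d}" for i in range(n)], name="cell_id")


class TestScreenPredictors:
    def test_identical_columns_one_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.random(100)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.random(100)})
        kept = em.screen_predictors(table, ["a", "b", "c"])
        assert len(kept) == 2 and "c" in kept

    def test_independent_noise_all_retained(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.random((200, 4)), columns=list("abcd"))
        assert em.screen_predictors(table, list("abcd")) == list("abcd")

    def test_drops_the_member_more_correlated_with_third(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(500)
        a = z + rng.standard_normal(500) * 0.3
        b = z + rng.standard_normal(500) * 0.3  # pair (a, b) has rho ~ 0.9
        c = b * 0.5 + rng.standard_normal(500)  # c leans towards b
        table = pd.DataFrame({"a": a, "b": b, "c": c})
        kept = em.screen_predictors(table, ["a", "b", "c"])
        assert kept == ["a", "c"]  # b dropped: larger mean |rho| to others


class TestTransformAndStandardize:
    def make_surfaces(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        idx = cells_index(n)
        return {
            "WE": MetricSurface("WE", pd.Series(rng.random(n) + 0.1, index=idx)),
            "sesPD": MetricSurface(
                "sesPD", pd.Series(rng.standard_normal(n), index=idx)
            ),
        }

    def make_cells(self, n=50, seed=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"elevation": rng.random(n) * 100, "slope": rng.random(n)},
            index=cells_index(n),
        )

    def test_output_standardized(self):
        frame = em.transform_and_standardize(
            self.make_surfaces(), self.make_cells(), ["elevation", "slope"]
        )
        assert np.allclose(frame.mean(), 0.0, atol=1e-12)
        assert np.allclose(frame.std(ddof=1), 1.0, atol=1e-12)

    def test_sespd_not_logged(self):
        surfaces = self.make_surfaces()
        frame = em.transform_and_standardize(
            surfaces, self.make_cells(), ["elevation"]
        )
        raw = surfaces["sesPD"].values
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        np.testing.assert_allclose(frame["sesPD"], expected)

    def test_nonpositive_response_error_names_cell_and_metric(self):
        idx = cells_index(3)
        surfaces = {
            "WE": MetricSurface("WE", pd.Series([1.0, 0.0, 2.0], index=idx))
        }
        cells = pd.DataFrame({"elevation": [1.0, 2.0, 3.0]}, index=idx)
        with pytest.raises(DataError, match="WE.*c0001"):
            em.transform_and_standardize(surfaces, cells, ["elevation"])

    def test_constant_predictor_rejected(self):
        cells = self.make_cells()
        cells["flat"] = 1.0
        with pytest.raises(DataError, match="flat"):
            em.transform_and_standardize(
                self.make_surfaces(), cells, ["elevation", "flat"]
            )


class TestAllSubsetsGLM:
    def test_exact_fit_best_model_contains_x(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        frame = pd.DataFrame({"x": x, "noise": rng.standard_normal(100), "y": x})
        models = em.all_subsets_glm("y", frame, ["x", "noise"])
        best = min(models, key=lambda m: m.aic)
        assert "x" in best.predictors
        full = [m for m in models if m.predictors == ("x",)][0]
        assert full.r_squared == pytest.approx(1.0)

    def test_model_count_is_two_to_the_p(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(
            rng.standard_normal((60, 8)), columns=[*"abcdefg", "y"]
        )
        models = em.all_subsets_glm("y", frame, list("abcdefg"))
        assert len(models) == 128

    def test_pure_noise_keeps_intercept_only_close(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {"a": rng.standard_normal(500), "b": rng.standard_normal(500),
             "y": rng.standard_normal(500)}
        )
        models = em.all_subsets_glm("y", frame, ["a", "b"])
        best = min(m.aic for m in models)
        null = [m for m in models if m.predictors == ()][0]
        assert null.aic - best < 4.0  # within a few AIC units of the best

    def test_orthonormal_slopes_equal_correlations(self):
        """With standardized orthogonal predictors, each slope in the full
        model equals the response-predictor correlation."""
        rng = np.random.default_rng(6)
        n = 4000
        frame = pd.DataFrame(
            {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}
        )
        frame = (frame - frame.mean()) / frame.std(ddof=1)
        frame["y"] = 0.4 * frame.a - 0.2 * frame.b + rng.standard_normal(n)
        frame["y"] = (frame.y - frame.y.mean()) / frame.y.std(ddof=1)
        full = [
            m for m in em.all_subsets_glm("y", frame, ["a", "b"])
            if m.predictors == ("a", "b")
        ][0]
        corr = frame.corr()
        assert full.coefficients["a"] == pytest.approx(corr.loc["y", "a"], abs=0.02)
        assert full.coefficients["b"] == pytest.approx(corr.loc["y", "b"], abs=0.02)

    def test_too_few_observations_rejected(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(DataError):
            em.all_subsets_glm("y", frame, ["a"])


class TestModelAverage:
    def test_single_model_passthrough(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        frame = pd.DataFrame({"x": x, "y": 2 * x + rng.normal(0, 0.1, 200)})
        models = em.all_subsets_glm("y", frame, ["x"])
        avg = em.model_average(models, delta_max=2.0)
        assert len(avg.retained) == 1
        best = min(models, key=lambda m: m.aic)
        assert avg.coefficients.loc["x", "estimate"] == pytest.approx(
            best.coefficients["x"]
        )
        assert avg.retained.weight.sum() == pytest.approx(1.0)

    def test_equal_aic_models_average_to_half_slope(self):
        a = em.FittedModel(
            predictors=("x",),
            coefficients=pd.Series({"intercept": 0.0, "x": 1.0}),
            std_errors=pd.Series({"intercept": 0.1, "x": 0.1}),
            rss=1.0, aic=10.0, r_squared=0.5, adj_r_squared=0.5, n=100,
        )
        b = em.FittedModel(
            predictors=(),
            coefficients=pd.Series({"intercept": 0.0}),
            std_errors=pd.Series({"intercept": 0.1}),
            rss=1.0, aic=10.0, r_squared=0.0, adj_r_squared=0.0, n=100,
        )
        avg = em.model_average([a, b])
        assert avg.coefficients.loc["x", "estimate"] == pytest.approx(0.5)
        # shrinkage average stays inside the per-model estimate range
        assert 0.0 <= avg.coefficients.loc["x", "estimate"] <= 1.0
        # unconditional SE blends sampling error and model spread
        expected_se = 0.5 * np.sqrt(0.1**2 + 0.25) + 0.5 * np.sqrt(0.25)
        assert avg.coefficients.loc["x", "se"] == pytest.approx(expected_se)

    def test_conditional_average_ignores_absent_models(self):
        a = em.FittedModel(
            predictors=("x",),
            coefficients=pd.Series({"intercept": 0.0, "x": 1.0}),
            std_errors=pd.Series({"intercept": 0.1, "x": 0.1}),
            rss=1.0, aic=10.0, r_squared=0.5, adj_r_squared=0.5, n=100,
        )
        b = em.FittedModel(
            predictors=(),
            coefficients=pd.Series({"intercept": 0.0}),
            std_errors=pd.Series({"intercept": 0.1}),
            rss=1.0, aic=10.0, r_squared=0.0, adj_r_squared=0.0, n=100,
        )
        avg = em.model_average([a, b], conditional=True)
        assert avg.coefficients.loc["x", "estimate"] == pytest.approx(1.0)

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(8)
        names = ["e", "d", "p"]
        beta = {"e": 0.25, "d": -0.2, "p": 0.1}
        n = 5000
        frame = pd.DataFrame(rng.standard_normal((n, 3)), columns=names)
        frame["y"] = sum(beta[k] * frame[k] for k in names) + rng.normal(
            0, 0.5, n
        )
        avg = em.model_average(em.all_subsets_glm("y", frame, names))
        for k, b in beta.items():
            est = avg.coefficients.loc[k, "estimate"]
            assert est == pytest.approx(b, abs=0.03)
            assert np.sign(est) == np.sign(b)


class TestSpearmanMatrix:
    def test_unit_diagonal_and_rank_invariance(self):
        rng = np.random.default_rng(9)
        idx = cells_index(80)
        base = pd.Series(rng.random(80) + 0.5, index=idx)
        surfaces = {
            "PD": MetricSurface("PD", base),
            "logPD": MetricSurface("logPD", np.log(base)),
            "noise": MetricSurface("noise", pd.Series(rng.random(80), index=idx)),
        }
        rho = em.spearman_matrix(surfaces)
        assert np.allclose(np.diag(rho), 1.0)
        assert rho.loc["PD", "logPD"] == pytest.approx(1.0)
        assert abs(rho.loc["PD", "noise"]) < 0.5
        assert np.allclose(rho, rho.T)


class TestSpeciesAreaFit:
    def test_exact_power_law(self):
        areas = np.array([10.0, 100.0, 1000.0, 5000.0])
        z, c = 0.3, 1.5
        richness = c * areas**z
        fit = em.species_area_fit(
            pd.DataFrame({"area": areas, "richness": richness})
        )
        assert fit.slope == pytest.approx(z)
        assert fit.adj_r_squared == pytest.approx(1.0)

    def test_shuffled_richness_has_no_signal(self):
        rng = np.random.default_rng(10)
        areas = np.array([82, 541, 701, 3640, 13, 2.8])
        richness = np.array([19, 39, 58, 109, 28, 17])
        r2 = []
        for _ in range(1000):
            fit = em.species_area_fit(
                pd.DataFrame(
                    {"area": areas, "richness": rng.permutation(richness)}
                )
            )
            r2.append(fit.adj_r_squared)
        assert abs(np.mean(r2)) < 0.15

    def test_recovers_generating_exponent(self):
        rng = np.random.default_rng(11)
        z_true = 0.25
        areas = np.array([13.0, 82.0, 541.0, 701.0, 2.8, 3640.0])
        slopes = []
        for _ in range(200):
            richness = 3.0 * areas**z_true * rng.lognormal(0, 0.15, size=6)
            fit = em.species_area_fit(
                pd.DataFrame({"area": areas, "richness": richness})
            )
            slopes.append(fit.slope)
        assert np.mean(slopes) == pytest.approx(z_true, abs=0.02)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(DataError):
            em.species_area_fit(
                pd.DataFrame({"area": [1.0, -2.0, 3.0],
                              "richness": [1.0, 2.0, 3.0]})
            )


class TestAnovaEdgeByCategory:
    def make_scores(self, groups):
        rows = []
        for cat, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"species": f"{cat}{i}", "iucn": cat, "EDGE": v})
        return pd.DataFrame(rows).set_index("species")

    def test_identical_groups_large_p(self):
        scores = self.make_scores(
            {"LC": [1.0, 2.0, 3.0], "EN": [1.0, 2.0, 3.0]}
        )
        f, p = em.anova_edge_by_category(scores)
        assert f == pytest.approx(0.0)
        assert p > 0.9

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(12)
        scores = self.make_scores(
            {"LC": rng.normal(0, 0.1, 20), "EN": rng.normal(10, 0.1, 20)}
        )
        _, p = em.anova_edge_by_category(scores)
        assert p < 1e-6

    def test_matches_manual_sums_of_squares(self):
        """Textbook one-way ANOVA on a hand-computed 3 x 3 table."""
        groups = {"LC": [1.0, 2.0, 3.0], "VU": [2.0, 3.0, 4.0],
                  "EN": [5.0, 6.0, 7.0]}
        scores = self.make_scores(groups)
        f, p = em.anova_edge_by_category(scores)
        # grand mean 33/9; SSB = 3*[(2-11/3)^2+(3-11/3)^2+(6-11/3)^2]
        means = {k: np.mean(v) for k, v in groups.items()}
        grand = 33.0 / 9.0
        ssb = 3 * sum((m - grand) ** 2 for m in means.values())
        ssw = sum(
            (x - means[k]) ** 2 for k, v in groups.items() for x in v
        )
        f_manual = (ssb / 2) / (ssw / 6)
        assert f == pytest.approx(f_manual)

    def test_dd_excluded_and_degenerate_rejected(self):
        scores = self.make_scores({"LC": [1.0, 2.0]})
        scores.loc["dd0"] = {"iucn": "DD", "EDGE": np.nan}
        with pytest.raises(DataError):
            em.anova_edge_by_category(scores)
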