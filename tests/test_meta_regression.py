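import numpy as np
import pandas as pd
import pytest

from metacontrol import (
    CollinearityError,
    ConfigurationError,
    DesignSpec,
    InvalidInputError,
    SyntheticConfig,
    analyze_outcome,
    build_design_matrix,
    fit_design,
    fit_meta_regression,
    fit_multivariable,
    fit_univariable_battery,
    generate_arms,
    pairwise_category_tests,
    pool_random_effects,
    significance_gate,
)
from metacontrol.meta_core import EffectRecord
from metacontrol.meta_regression import design_from_frame
from oracles import grid_reml_tau2, wls_fit


def _frame(levels, follow_up=None):
    data = {"species": levels}
    if follow_up is not None:
        data["follow_up_hours"] = follow_up
    return pd.DataFrame(data)


class TestDesignMatrix:
    def test_three_level_moderator_gives_two_dummies(self):
        rng = np.random.default_rng(0)
        levels = ["dog"] * 4 + ["pig"] * 4 + ["sheep"] * 2
        dm = design_from_frame(_frame(levels), rng.normal(50, 5, 10), np.ones(10), ["species"])
        assert dm.X.shape == (10, 3)
        assert dm.canonical_labels == ["intercept", "species:pig", "species:sheep"]

    def test_single_level_moderator_collapses_to_intercept(self, caplog):
        with caplog.at_level("WARNING"):
            dm = design_from_frame(_frame(["pig"] * 6), np.arange(6.0), np.ones(6), ["species"])
        assert dm.X.shape == (6, 1)
        assert any("single observed level" in r.message for r in caplog.records)

    def test_reference_labels_match_table_phrasing(self):
        levels = ["dog"] * 4 + ["pig"] * 4 + ["sheep"] * 2
        dm = design_from_frame(
            _frame(levels), np.arange(10.0), np.ones(10), ["species"], {"species": "dog"}
        )
        assert dm.labels == ["intercept", "pig (vs dog)", "sheep (vs dog)"]

    def test_unknown_reference_level_rejected(self):
        with pytest.raises(ConfigurationError, match="reference level"):
            design_from_frame(
                _frame(["dog", "pig"] * 3), np.arange(6.0), np.ones(6),
                ["species"], {"species": "sheep"},
            )

    def test_missing_moderator_rows_dropped_with_count(self):
        fu = [24.0, None, 168.0, None, 72.0, 336.0]
        dm = design_from_frame(
            _frame(["dog", "pig"] * 3, fu), np.arange(6.0), np.ones(6),
            ["species", "follow_up_hours"],
        )
        assert dm.n_dropped == 2 and dm.X.shape[0] == 4


class TestFitMetaRegression:
    def test_intercept_only_reduces_to_pooling(self, five_effects):
        y = np.array([e.estimate for e in five_effects])
        v = np.array([e.variance for e in five_effects])
        fit = fit_meta_regression(y, v, np.ones((5, 1)), ["intercept"])
        pooled = pool_random_effects(five_effects)
        assert fit.coefficients["intercept"] == pytest.approx(pooled.mu, rel=1e-9)
        assert fit.omnibus_p is None and fit.r2 == 0.0

    def test_six_row_wls_oracle_equivalence(self):
        y = np.array([40.0, 62.1, 44.3, 58.7, 41.9, 60.2])
        v = np.array([2.0, 3.0, 1.5, 4.0, 2.5, 3.5])
        X = np.column_stack([np.ones(6), [0, 1, 0, 1, 0, 1.0]])
        t2 = grid_reml_tau2(y, v, X=X, upper=20.0, step=1e-3)
        beta_o, cov_o = wls_fit(y, v, X, t2)
        fit = fit_meta_regression(y, v, X, ["intercept", "pig"])
        assert fit.coefficients["intercept"] == pytest.approx(beta_o[0], abs=1e-3)
        assert fit.coefficients["pig"] == pytest.approx(beta_o[1], abs=1e-3)
        assert np.allclose(fit.cov_matrix, cov_o, atol=1e-3)

    def test_recovers_large_categorical_effect_with_small_noise(self):
        rng = np.random.default_rng(21)
        pig = rng.integers(0, 2, 200).astype(float)
        y = 40.0 + 21.6 * pig + rng.normal(0, 0.3, 200)
        v = np.full(200, 0.09)
        fit = fit_meta_regression(y, v, np.column_stack([np.ones(200), pig]), ["intercept", "pig"])
        assert fit.coefficients["pig"] == pytest.approx(21.6, abs=1.0)

    def test_rank_deficiency_names_aliased_terms(self):
        X = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(CollinearityError, match="aliased"):
            fit_meta_regression(np.arange(8.0), np.ones(8), X, ["intercept", "a", "b"])

    def test_weight_override_is_scale_free(self):
        rng = np.random.default_rng(5)
        y = rng.normal(10, 2, 20)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        w = rng.uniform(1, 30, 20)
        f1 = fit_meta_regression(y, np.ones(20), X, ["intercept", "x"], weights_override=w)
        f2 = fit_meta_regression(y, np.ones(20), X, ["intercept", "x"], weights_override=2 * w)
        assert f1.coefficients == pytest.approx(f2.coefficients, rel=1e-9)

    def test_r2_is_zero_for_pure_noise_moderator(self):
        """Median R^2 over 200 replicates of a non-informative moderator < 0.05."""
        rng = np.random.default_rng(99)
        r2s = []
        for _ in range(200):
            y = 50 + rng.normal(0, 5, 50) + rng.normal(0, 1, 50)
            X = np.column_stack([np.ones(50), rng.normal(size=50)])
            r2s.append(fit_meta_regression(y, np.ones(50), X, ["intercept", "noise"]).r2)
        assert np.median(r2s) < 0.05
        assert all(0.0 <= r <= 1.0 for r in r2s)


class TestContrasts:
    def _fit(self, seed=4, k=60):
        cfg = SyntheticConfig(
            k_studies=k, seed=seed, tau2_true=25.0,
            true_betas={"species:pig": 10.0, "species:sheep": -8.0},
            level_probabilities={
                **SyntheticConfig().level_probabilities,
                "species": {"dog": 0.4, "pig": 0.4, "sheep": 0.2},
            },
        )
        return generate_arms(cfg)

    def test_three_level_moderator_yields_three_contrasts(self):
        ds = self._fit()
        spec = DesignSpec(moderators=["species"], add_separately=[])
        fit = fit_design(build_design_matrix(ds, spec, "IS_AAR"))
        assert len(pairwise_category_tests(fit, "species")) == 3

    def test_two_level_pairwise_p_equals_omnibus_p(self):
        rng = np.random.default_rng(8)
        pig = rng.integers(0, 2, 40).astype(float)
        y = 45 + 5 * pig + rng.normal(0, 4, 40)
        frame = pd.DataFrame({"species": np.where(pig > 0, "pig", "dog")})
        dm = design_from_frame(frame, y, np.ones(40), ["species"], {"species": "dog"})
        fit = fit_design(dm)
        (contrast,) = pairwise_category_tests(fit, "species")
        assert contrast.p == pytest.approx(fit.omnibus_p, abs=1e-10)

    def test_reference_level_choice_leaves_contrasts_identical(self):
        ds = self._fit(seed=13)
        results = {}
        for ref in ("dog", "pig", "sheep"):
            spec = DesignSpec(moderators=["species"], add_separately=[],
                              reference_levels={"species": ref})
            fit = fit_design(build_design_matrix(ds, spec, "IS_AAR"))
            results[ref] = {
                c.label: (c.estimate, c.se, c.p) for c in pairwise_category_tests(fit, "species")
            }
        for ref in ("pig", "sheep"):
            for label, (est, se, p) in results[ref].items():
                est0, se0, p0 = results["dog"][label]
                assert est == pytest.approx(est0, abs=1e-10)
                assert se == pytest.approx(se0, abs=1e-10)
                assert p == pytest.approx(p0, abs=1e-10)

    def test_row_order_invariance(self):
        ds = self._fit(seed=14)
        spec = DesignSpec(moderators=["species"], add_separately=[])
        fit1 = fit_design(build_design_matrix(ds, spec, "IS_AAR"))
        ds.arms = list(reversed(ds.arms))
        fit2 = fit_design(build_design_matrix(ds, spec, "IS_AAR"))
        for t in fit1.term_labels:
            assert fit1.coefficients[t] == pytest.approx(fit2.coefficients[t], rel=1e-8)

    def test_unknown_moderator_rejected(self):
        ds = self._fit()
        spec = DesignSpec(moderators=["species"], add_separately=[])
        fit = fit_design(build_design_matrix(ds, spec, "IS_AAR"))
        with pytest.raises(ConfigurationError):
            pairwise_category_tests(fit, "vessel")


class TestBatteryAndMultivariable:
    def test_univariable_battery_row_counts(self, small_dataset):
        res = fit_univariable_battery(
            small_dataset, "IS_AAR", moderators=["species", "occlusion", "follow_up_hours"]
        )
        for m in ("species", "occlusion"):
            levels = {getattr(a, m) for a in small_dataset.arms}
            assert len(res[m].subgroups) == len(levels)
        assert res["follow_up_hours"].subgroups.empty

    def test_only_true_moderator_flags_significant(self):
        """With one strong true effect, that moderator's omnibus p is small
        while a pure-noise moderator's stays typically non-significant."""
        hits_true = 0
        for rep in range(10):
            cfg = SyntheticConfig(
                k_studies=120, seed=500 + rep, tau2_true=25.0,
                true_betas={"species:pig": 21.6},
                level_probabilities={
                    **SyntheticConfig().level_probabilities,
                    "species": {"dog": 0.5, "pig": 0.5, "sheep": 0.0},
                },
            )
            ds = generate_arms(cfg)
            res = fit_univariable_battery(ds, "IS_AAR", moderators=["species"])
            if significance_gate(res["species"].fit.omnibus_p):
                hits_true += 1
        assert hits_true >= 8

    def test_multivariable_with_separate_ischemia(self, small_dataset):
        spec = DesignSpec(
            moderators=["species", "follow_up_hours", "ischemia_minutes"],
            add_separately=["ischemia_minutes"],
        )
        joint, separate = fit_multivariable(small_dataset, "IS_AAR", spec)
        assert "ischemia_minutes" not in joint.term_labels
        assert "ischemia_minutes" in separate
        assert "ischemia_minutes" in separate["ischemia_minutes"].term_labels
        # ischemia only exists for temporary occlusion: the separate fit
        # uses the complete-case subset
        n_temp = sum(
            a.occlusion == "temporary" for a in small_dataset.arms if a.outcome == "IS_AAR"
        )
        assert separate["ischemia_minutes"].k == n_temp

    def test_no_separate_moderators_means_empty_mapping(self, small_dataset):
        spec = DesignSpec(moderators=["species"], add_separately=[])
        _, separate = fit_multivariable(small_dataset, "IS_AAR", spec)
        assert separate == {}


class TestSignificanceGate:
    @pytest.mark.parametrize("p, expected", [(0.049, True), (0.05, False), (0.33, False)])
    def test_strict_threshold(self, p, expected):
        assert significance_gate(p) is expected

    def test_invalid_p_rejected(self):
        with pytest.raises(InvalidInputError):
            significance_gate(1.2)

    def test_non_significant_multivariable_skips_posthoc(self):
        cfg = SyntheticConfig(
            k_studies=100, seed=424, tau2_true=25.0,
            level_probabilities={
                **SyntheticConfig().level_probabilities,
                "species": {"dog": 0.5, "pig": 0.4, "sheep": 0.1},
            },
        )
        ds = generate_arms(cfg)
        spec = DesignSpec(moderators=["species"], add_separately=[])
        report = analyze_outcome(ds, "IS_AAR", spec)
        assert not significance_gate(report.joint.omnibus_p)
        assert report.posthoc_skipped and report.posthoc == {}
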