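"""Mixed-effects fits, coefficient pruning, post hocs and model t-tests."""

import numpy as np
import pytest

import curvesprint as cs

SPEC_MAIN = cs.LmemSpec(response="vmax", fixed=["radius", "direction"])
SPEC_INT = cs.LmemSpec(
    response="vmax", fixed=["radius", "direction"], interactions=[("radius", "direction")]
)


class TestFitLmem:
    def test_direction_effect_within_ci(self):
        df = cs.vmax_table(direction_effect=0.14, noise_sd=0.15, n_trials=3, seed=7)
        fit = cs.fit_lmem(df, SPEC_MAIN)
        coef = fit.coef("C(direction)[T.CW]")
        # CW is coded against CCW, so the coefficient estimates -0.14
        assert abs(coef.estimate + 0.14) <= 1.96 * coef.se

    def test_duplicated_rows_keep_point_estimates(self):
        df = cs.vmax_table(seed=2)
        fit1 = cs.fit_lmem(df, SPEC_MAIN)
        fit2 = cs.fit_lmem(
            df.loc[df.index.repeat(2)].reset_index(drop=True), SPEC_MAIN
        )
        np.testing.assert_allclose(
            fit1.coefficients.estimate, fit2.coefficients.estimate, atol=1e-6
        )

    def test_null_effects_rarely_significant(self):
        """Type-I behaviour: with all effects zero, fixed-effect p-values
        exceed 0.05 in at least 90% of seeds."""
        ok = 0
        n = 60
        for seed in range(n):
            df = cs.vmax_table(
                direction_effect=0.0,
                radius_effects={17.2: 0.0, 36.5: 0.0},
                noise_sd=0.15,
                seed=1000 + seed,
            )
            fit = cs.fit_lmem(df, SPEC_MAIN)
            ps = fit.coefficients[fit.coefficients.name != "Intercept"].p
            ok += int((ps > 0.05).all())
        assert ok >= 0.9 * n * 0.9  # two factors, jointly >90% each

    def test_requires_two_athletes(self):
        df = cs.vmax_table(seed=1)
        with pytest.raises(ValueError, match="athletes"):
            cs.fit_lmem(df[df.athlete == "S01"], SPEC_MAIN)


class TestPrune:
    def test_null_interaction_removed(self):
        df = cs.vmax_table(interaction=0.0, seed=5)
        pruned = cs.prune(cs.fit_lmem(df, SPEC_INT))
        assert pruned.spec.interactions == []
        assert len(pruned.pruning_log) == 1
        # main effects retained
        assert pruned.coefficients.name.str.contains("C(radius)", regex=False).any()

    def test_strong_interaction_retained(self):
        df = cs.vmax_table(interaction=0.6, seed=5)
        pruned = cs.prune(cs.fit_lmem(df, SPEC_INT))
        assert pruned.spec.interactions == [("radius", "direction")]

    def test_fixed_point(self):
        df = cs.vmax_table(interaction=0.0, seed=5)
        once = cs.prune(cs.fit_lmem(df, SPEC_INT))
        twice = cs.prune(once)
        assert twice.spec.interactions == once.spec.interactions
        np.testing.assert_allclose(
            once.coefficients.estimate, twice.coefficients.estimate
        )


class TestPosthoc:
    def _family(self):
        return [
            ("CCW-CW @17.2", {"radius": 17.2, "direction": "CCW"}, {"radius": 17.2, "direction": "CW"}),
            ("CCW-CW @36.5", {"radius": 36.5, "direction": "CCW"}, {"radius": 36.5, "direction": "CW"}),
            ("17.2-36.5 @CCW", {"radius": 17.2, "direction": "CCW"}, {"radius": 36.5, "direction": "CCW"}),
            ("17.2-36.5 @CW", {"radius": 17.2, "direction": "CW"}, {"radius": 36.5, "direction": "CW"}),
        ]

    def test_family_of_four_gives_alpha_0125(self):
        df = cs.vmax_table(interaction=0.6, seed=5)
        fit = cs.fit_lmem(df, SPEC_INT)
        table = cs.posthoc_bonferroni(fit, self._family())
        assert (table.alpha_corrected == 0.0125).all()
        assert len(table) == 4

    def test_family_of_one_keeps_alpha(self):
        df = cs.vmax_table(interaction=0.6, seed=5)
        fit = cs.fit_lmem(df, SPEC_INT)
        table = cs.posthoc_bonferroni(fit, self._family()[:1])
        assert table.alpha_corrected.iloc[0] == 0.05

    def test_self_contrast_is_zero(self):
        df = cs.vmax_table(interaction=0.6, seed=5)
        fit = cs.fit_lmem(df, SPEC_INT)
        cell = {"radius": 17.2, "direction": "CCW"}
        table = cs.posthoc_bonferroni(fit, [("self", cell, dict(cell))])
        assert table.estimate.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_simple_effect(self):
        df = cs.vmax_table(interaction=0.6, direction_effect=0.14, seed=5, noise_sd=0.1)
        fit = cs.fit_lmem(df, SPEC_INT)
        table = cs.posthoc_bonferroni(fit, self._family()).set_index("contrast")
        # CCW-CW at 17.2 carries effect + interaction; at 36.5 effect only
        assert table.loc["CCW-CW @17.2", "estimate"] == pytest.approx(0.74, abs=0.1)
        assert table.loc["CCW-CW @36.5", "estimate"] == pytest.approx(0.14, abs=0.1)

    def test_empty_family_rejected(self):
        df = cs.vmax_table(seed=5)
        fit = cs.fit_lmem(df, SPEC_MAIN)
        with pytest.raises(ValueError, match="empty"):
            cs.posthoc_bonferroni(fit, [])


class TestCompareModels:
    def test_identical_vectors_tie(self):
        x = np.array([10.0, 9.5, 8.0, 11.0])
        rep = cs.compare_models_ttest(x, x, "m")
        assert rep["mean_difference"] == 0.0
        assert rep["p"] == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(3)
        pred = np.full(9, 5.0)
        meas = pred + 1.0 + rng.normal(0, 0.01, 9)
        rep = cs.compare_models_ttest(meas, pred, "m")
        # closed-form t = mean / (sd/sqrt(n)) is enormous here
        assert rep["p"] < 1e-3
        assert rep["mean_difference"] == pytest.approx(1.0, abs=0.02)

    def test_true_model_kept_biased_model_rejected(self):
        rng = np.random.default_rng(12)
        V = 9.12 + 0.6 * rng.standard_normal(9)
        truth = np.array([cs.percent_slowing(v, cs.greene_vmax(v, 17.2)) for v in V])
        measured = truth + rng.normal(0, 0.3, 9)
        good = cs.compare_models_ttest(measured, truth, "greene")
        biased = cs.compare_models_ttest(measured, truth - 1.5, "biased")
        assert good["p"] > 0.05
        assert biased["p"] < 0.01
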