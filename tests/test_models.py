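"""Curve v_max models: limits, monotonicity, independent solve oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

import curvesprint as cs
from curvesprint.models import ModelDomainError

G = 9.81
KIN = dict(t_a=0.115, L_c=1.00, t_step=0.23, t_swing=0.345)


def _mcmahon_oracle(V, t_a, L_c, t_step, r, g=G):
    """Independent brentq solve of the aerial-time-compression balance."""

    def f(v):
        gp = np.hypot(g, v**2 / r)
        return v * (t_step - t_a * g / gp) - V * (t_step - t_a)

    return brentq(f, 1e-6, V, xtol=1e-12)


def _usherwood_oracle(V, t_swing, L_c, r, g=G):
    f_bw = 0.5 * (V * t_swing / L_c + 1)

    def f(v):
        gp_ratio = np.hypot(1.0, v**2 / (g * r))
        return v * (2 * f_bw - 1) * gp_ratio - V * (2 * f_bw - gp_ratio)

    return brentq(f, 1e-6, V, xtol=1e-12)


class TestGreene:
    def test_printed_predictions_at_group_mean(self):
        # constant-force model at the group-mean straight v_max
        s17 = cs.percent_slowing(9.12, cs.greene_vmax(9.12, 17.2, G))
        s36 = cs.percent_slowing(9.12, cs.greene_vmax(9.12, 36.5, G))
        assert round(s17, 1) == 6.8
        assert round(s36, 1) == 1.0

    def test_infinite_radius_limit(self):
        assert cs.greene_vmax(9.12, 1e9, G) == pytest.approx(9.12, abs=1e-6)

    def test_depends_only_on_v_r_g(self):
        meas = pd.DataFrame(
            [
                {"subject_id": "a", "v_straight": 9.0, **KIN},
                {"subject_id": "b", "v_straight": 9.0, "t_a": 0.2, "L_c": 0.8,
                 "t_step": 0.3, "t_swing": 0.5},
            ]
        )
        preds = cs.predict_session(meas, [17.2])
        greene = preds[preds.model == cs.GREENE]
        assert greene.v_pred.nunique() == 1

    def test_non_physical_inputs_rejected(self):
        with pytest.raises(ModelDomainError):
            cs.greene_vmax(-1.0, 17.2)
        with pytest.raises(ModelDomainError):
            cs.greene_vmax(9.12, 1.0)


class TestMcMahon:
    def test_infinite_radius_limit(self):
        v = cs.mcmahon_vmax(9.0, r=1e9, g=G, **{k: KIN[k] for k in ("t_a", "L_c", "t_step")})
        assert v == pytest.approx(9.0, abs=1e-6)

    def test_matches_independent_solve(self):
        for V, r in [(9.0, 17.2), (9.0, 36.5), (8.2, 25.0), (10.0, 50.0)]:
            mine = cs.mcmahon_vmax(V, 0.12, 1.00, 0.23, r, G)
            oracle = _mcmahon_oracle(V, 0.12, 1.00, 0.23, r, G)
            assert mine == pytest.approx(oracle, abs=1e-7)

    def test_monotone_in_radius(self):
        vs = [cs.mcmahon_vmax(9.0, 0.12, 1.0, 0.23, r, G) for r in (10, 17.2, 36.5, 100)]
        assert all(a < b for a, b in zip(vs, vs[1:]))

    def test_domain_error_names_quantity(self):
        with pytest.raises(ModelDomainError, match="t_a"):
            cs.mcmahon_vmax(9.0, t_a=0.3, L_c=1.0, t_step=0.23, r=17.2)


class TestUsherwood:
    def test_infinite_radius_limit(self):
        v = cs.usherwood_vmax(9.0, 0.35, 1.0, 1e9, G)
        assert v == pytest.approx(9.0, abs=1e-6)

    def test_matches_independent_solve(self):
        for V, r in [(9.0, 36.5), (9.0, 17.2), (8.5, 20.0)]:
            mine = cs.usherwood_vmax(V, 0.35, 1.00, r, G)
            oracle = _usherwood_oracle(V, 0.35, 1.00, r, G)
            assert mine == pytest.approx(oracle, abs=1e-7)

    def test_tighter_curves_slow_more(self):
        s = {
            r: cs.percent_slowing(9.0, cs.usherwood_vmax(9.0, 0.35, 1.0, r, G))
            for r in (17.2, 36.5)
        }
        assert s[17.2] > s[36.5]


def test_all_models_monotone_and_consistent_at_infinity():
    radii = np.geomspace(12, 1e6, 25)
    for name, fn in [
        (cs.GREENE, lambda r: cs.greene_vmax(9.12, r, G)),
        (cs.MCMAHON, lambda r: cs.mcmahon_vmax(9.12, 0.115, 1.0, 0.23, r, G)),
        (cs.USHERWOOD, lambda r: cs.usherwood_vmax(9.12, 0.345, 1.0, r, G)),
    ]:
        vs = np.array([fn(r) for r in radii])
        assert np.all(np.diff(vs) >= -1e-9), name
        assert vs[-1] == pytest.approx(9.12, abs=1e-6), name
        assert np.all(vs <= 9.12 + 1e-9), name


def test_constant_force_model_predicts_least_slowing():
    """The force-only model is the most optimistic at both study radii."""
    for r in (17.2, 36.5):
        greene = cs.greene_vmax(9.12, r, G)
        mcmahon = cs.mcmahon_vmax(9.12, r=r, g=G, t_a=0.115, L_c=1.0, t_step=0.23)
        usherwood = cs.usherwood_vmax(9.12, 0.345, 1.0, r, G)
        assert greene > mcmahon and greene > usherwood


class TestPredictSession:
    def test_table_shape_single_subject(self):
        meas = pd.DataFrame([{"subject_id": "s1", "v_straight": 9.12, **KIN}])
        preds = cs.predict_session(meas, [17.2, 36.5])
        assert len(preds) == 6  # 3 models x 2 radii
        assert set(preds.model) == set(cs.MODEL_NAMES)

    def test_identical_subjects_zero_spread(self):
        meas = pd.DataFrame(
            [{"subject_id": f"s{i}", "v_straight": 9.12, **KIN} for i in range(4)]
        )
        summ = cs.group_summary(cs.predict_session(meas, [17.2]))
        assert (summ.slowing_sd.fillna(0) == 0).all()

    def test_missing_kinematics_flags_kinematic_models_only(self):
        meas = pd.DataFrame([{"subject_id": "s1", "v_straight": 9.12}])
        preds = cs.predict_session(meas, [17.2]).set_index("model")
        assert np.isfinite(preds.loc[cs.GREENE, "v_pred"])
        assert np.isnan(preds.loc[cs.MCMAHON, "v_pred"])
        assert np.isnan(preds.loc[cs.USHERWOOD, "v_pred"])

    def test_group_mean_at_study_spread(self):
        rng = np.random.default_rng(0)
        meas = pd.DataFrame(
            [
                {"subject_id": f"s{i}", "v_straight": v, **KIN}
                for i, v in enumerate(9.12 + 0.60 * rng.standard_normal(9))
            ]
        )
        summ = cs.group_summary(cs.predict_session(meas, [36.5])).set_index("model")
        assert summ.loc[cs.GREENE, "slowing_mean"] == pytest.approx(1.0, abs=0.3)


def test_radius_sweep_table():
    df = cs.radius_sweep(9.12, 15, 200, 8, **KIN)
    assert len(df) == 8
    for col in cs.MODEL_NAMES:
        assert df[col].is_monotonic_increasing
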