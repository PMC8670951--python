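import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from axialgrowth.data_model import SpecimenMeasurement
from axialgrowth.growth_gradients import (GradientObservations, aicc,
                                          akaike_weights, compare_models,
                                          evidential_ratio,
                                          fit_gradient_model, pyl_stasis_test,
                                          sg_a_predict, sg_r_predict,
                                          tg_position_map, tg_predict)

from conftest import SGA_PARAMS, TGT_PARAMS


class TestSGR:
    def test_constant_field(self):
        for s in range(1, 13):
            for i in range(1, s + 1):
                assert sg_r_predict(0.1, 1.0, 1.0, i, s) == pytest.approx(0.1)

    def test_r_one_is_pure_release_pattern(self):
        for i in (1, 3, 5):
            vals = {float(sg_r_predict(0.1, 0.9, 1.0, i, s))
                    for s in range(i, 13)}
            assert len({round(v, 15) for v in vals}) == 1

    def test_recursion_oracle(self):
        A, B, r = 0.11, 0.85, 0.97
        for i in range(1, 13):
            val = A * B ** (i - 1)  # release size at s = i
            for s in range(i, 13):
                assert sg_r_predict(A, B, r, i, s) == pytest.approx(
                    val, rel=1e-12)
                val *= r

    def test_unreleased_segment_is_error(self):
        with pytest.raises(ValueError):
            sg_r_predict(0.1, 1.0, 1.0, 5, 4)


class TestSGA:
    TRL = {s: 0.9 * 1.25 ** s for s in range(1, 14)}

    def test_isometric_limit(self):
        vals = [sg_a_predict(0.1, 0.9, 1.0, 2, s, self.TRL)
                for s in range(2, 13)]
        assert np.allclose(vals, vals[0])

    def test_telescoping_oracle(self):
        A, B, k = 0.1, 0.9, 0.8
        i, s = 2, 9
        trg_prod = 1.0
        for t in range(i, s):
            trg_prod *= (self.TRL[t + 1] / self.TRL[t]) ** (k - 1.0)
        expect = A * B ** (i - 1) * trg_prod
        assert sg_a_predict(A, B, k, i, s, self.TRL) == pytest.approx(
            expect, rel=1e-12)

    def test_sub_isometric_decreases_with_stage(self):
        vals = [float(sg_a_predict(0.1, 0.9, 0.7, 2, s, self.TRL))
                for s in range(2, 13)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_missing_covariate_is_error(self):
        with pytest.raises(ValueError, match="covariate"):
            sg_a_predict(0.1, 0.9, 0.8, 1, 5, {1: 1.0})


class TestPositionMap:
    @given(st.floats(-10, 10))
    @settings(max_examples=60, deadline=None)
    def test_endpoints_fixed(self, b):
        assert tg_position_map(0.0, b) == pytest.approx(0.0, abs=1e-12)
        assert tg_position_map(1.0, b) == pytest.approx(1.0, rel=1e-12)

    def test_small_b_is_identity(self):
        p = np.linspace(0, 1, 21)
        assert np.max(np.abs(tg_position_map(p, 1e-8) - p)) <= 1e-7
        assert np.allclose(tg_position_map(p, 0.0), p)

    def test_quadrature_oracle(self):
        b, p = 2.0, 0.5
        val = tg_position_map(p, b)
        assert val == pytest.approx(0.26894, abs=5e-6)
        num = quad(lambda u: math.exp(b * u), 0, p)[0]
        den = quad(lambda u: math.exp(b * u), 0, 1)[0]
        assert val == pytest.approx(num / den, abs=1e-10)

    @given(st.floats(0.001, 0.999), st.floats(-8, 8))
    @settings(max_examples=100, deadline=None)
    def test_map_stays_in_unit_interval_and_monotone(self, p, b):
        v = tg_position_map(p, b)
        assert 0.0 < v < 1.0
        assert tg_position_map(min(p + 1e-3, 0.9999), b) > v


class TestTGPredict:
    def test_frozen_boundaries_when_gradient_zero(self):
        table = tg_predict(0.0, 0.0, 0.5, 0.9, stages=range(1, 13),
                           link="stage", response="RPS")
        for (i, s), v in table.items():
            assert v == pytest.approx(1.0 - 0.5 * 0.9 ** i, rel=1e-12)

    def test_positive_gradient_drifts_boundaries_anteriorly(self):
        table = tg_predict(0.8, 0.0, 0.5, 0.9, stages=range(1, 13),
                           link="stage", response="RPS")
        for i in range(1, 12):
            series = [table[(i, s)] for s in range(i, 13)]
            assert all(b < a for a, b in zip(series, series[1:]))

    def test_boundaries_never_cross_random_params(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            # admissible = anteriorward drift (b_s >= 0 over fitted stages),
            # under which the release boundary always enters behind its
            # predecessor and the monotone map preserves the ordering
            c0 = rng.uniform(0.0, 1.0)
            c1 = rng.uniform(0.0, 0.1)
            q0 = rng.uniform(0.2, 0.7)
            q1 = rng.uniform(0.75, 0.99)
            table = tg_predict(c0, c1, q0, q1, stages=range(1, 13),
                               link="stage", response="RPS")
            for s in range(1, 13):
                col = [table[(i, s)] for i in range(1, s + 1)]
                assert all(b > a for a, b in zip(col, col[1:]))
                assert all(0 < v < 1 for v in col)

    def test_differencing_reproduces_rls(self):
        rps = tg_predict(*[TGT_PARAMS[k] for k in ("c0", "c1", "q0", "q1")],
                         stages=range(1, 13), link="stage", response="RPS")
        rls = tg_predict(*[TGT_PARAMS[k] for k in ("c0", "c1", "q0", "q1")],
                         stages=range(1, 13), link="stage", response="RLS")
        for s in range(1, 13):
            total = sum(rls[(i, s)] for i in range(1, s + 1))
            assert total == pytest.approx(rps[(s, s)], rel=1e-12)
            assert total <= 1.0

    def test_bad_initial_condition_names_parameters(self):
        with pytest.raises(ValueError, match="q0=2"):
            tg_predict(0.0, 0.0, 2.0, 1.0, stages=range(1, 13), link="stage")

    def test_tgt_needs_trg_series(self):
        with pytest.raises(ValueError, match="TRG"):
            tg_predict(0.1, 0.1, 0.5, 0.9, stages=range(1, 13), link="trg")


class TestFitGradientModel:
    def test_sga_zero_noise_recovery(self, sga_zero_noise_summaries):
        obs = GradientObservations.from_summaries(sga_zero_noise_summaries,
                                                  response="RLS")
        fit = fit_gradient_model("SG-A", obs)
        assert fit.rss <= 1e-20
        for name in ("A", "B", "k"):
            assert fit.params[name] == pytest.approx(SGA_PARAMS[name],
                                                     rel=1e-6)

    def test_tgt_zero_noise_recovery_and_separation(self,
                                                    tgt_zero_noise_summaries):
        obs = GradientObservations.from_summaries(tgt_zero_noise_summaries,
                                                  response="RLS")
        fit = fit_gradient_model("TG-T", obs)
        for name, true in TGT_PARAMS.items():
            assert fit.params[name] == pytest.approx(true, rel=1e-4)
        sgr = fit_gradient_model("SG-R", obs)
        assert sgr.rss > fit.rss * 1e3

    def test_observation_order_invariance(self, sga_zero_noise_summaries):
        obs = GradientObservations.from_summaries(sga_zero_noise_summaries,
                                                  response="RLS")
        rng = np.random.default_rng(1)
        perm = rng.permutation(obs.n)
        shuffled = GradientObservations(
            index=[obs.index[j] for j in perm], values=obs.values[perm],
            response="RLS", trl_series=obs.trl_series)
        a = fit_gradient_model("SG-A", obs)
        b = fit_gradient_model("SG-A", shuffled)
        for name in a.params:
            assert a.params[name] == pytest.approx(b.params[name], rel=1e-9)

    def test_rps_response_rejected_for_sg(self, tgt_zero_noise_summaries):
        obs = GradientObservations.from_summaries(tgt_zero_noise_summaries,
                                                  response="RPS")
        with pytest.raises(ValueError, match="RLS"):
            fit_gradient_model("SG-A", obs)

    def test_fitted_parameters_respect_invariants(self, noisy_specs):
        from axialgrowth.data_model import stage_summaries
        obs = GradientObservations.from_summaries(stage_summaries(noisy_specs),
                                                  response="RLS",
                                                  stages=range(1, 13))
        for model in ("SG-R", "SG-A", "TG-T", "TG-D"):
            fit = fit_gradient_model(model, obs)
            p = fit.params
            if model == "SG-R":
                assert p["A"] > 0 and p["B"] > 0 and p["r"] > 0
            elif model == "SG-A":
                assert p["A"] > 0 and p["B"] > 0
            else:
                for i in range(1, 13):
                    assert 0 < p["q0"] * p["q1"] ** i < 1


class TestModelComparison:
    def test_equal_scores_split_weights(self):
        w = akaike_weights([10.0, 10.0])
        assert w == pytest.approx([0.5, 0.5])
        assert evidential_ratio(w[0], w[1]) == pytest.approx(1.0)

    @given(st.lists(st.floats(-1000, 1000), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_weights_normalize(self, scores):
        w = akaike_weights(scores)
        assert abs(w.sum() - 1.0) <= 1e-12
        assert np.all(w >= 0)

    def test_aicc_approaches_aic(self):
        n, k_model, rss = 10 ** 6, 3, 123.4
        k = k_model + 1
        aic = n * math.log(rss / n) + 2 * k
        assert abs(aicc(rss, n, k_model) - aic) <= 1e-3

    def test_mixed_responses_rejected(self, sga_zero_noise_summaries,
                                      tgt_zero_noise_summaries):
        obs_rls = GradientObservations.from_summaries(
            sga_zero_noise_summaries, response="RLS")
        obs_rps = GradientObservations.from_summaries(
            tgt_zero_noise_summaries, response="RPS")
        a = fit_gradient_model("SG-A", obs_rls)
        b = fit_gradient_model("TG-T", obs_rps)
        with pytest.raises(ValueError, match="response"):
            compare_models([a, b])

    def test_comparison_table_contents(self, sga_zero_noise_summaries):
        obs = GradientObservations.from_summaries(sga_zero_noise_summaries,
                                                  response="RLS")
        fits = [fit_gradient_model(m, obs)
                for m in ("SG-A", "SG-R", "TG-T", "TG-D")]
        df = compare_models(fits)
        assert df.iloc[0]["model"] == "SG-A"
        assert df.iloc[0]["dAICc"] == 0.0
        assert df["wAICc"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (df["pct_variance"] <= 100.0).all()
        assert set(df["n_par"]) == {3, 4}


class TestPylStasis:
    def _spec(self, sid, degree, pyl):
        return SpecimenMeasurement(specimen_id=sid, period="meraspid",
                                   degree=degree, lts=(0.1,) * degree,
                                   pyl=pyl)

    def test_exactly_constant_pyl(self):
        specs = [self._spec(f"s{j}", d, 0.55)
                 for j, d in enumerate([1, 1, 2, 3, 3])]
        res = pyl_stasis_test(specs, (0, 10))
        assert res.slope == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_closed_form_oracle(self):
        from scipy.stats import linregress
        stages = [1, 2, 3, 4]
        pyls = [1.0, 1.1, 0.9, 1.0]
        specs = [self._spec(f"s{d}", d, p) for d, p in zip(stages, pyls)]
        res = pyl_stasis_test(specs, (0, 10))
        oracle = linregress(stages, pyls)
        assert res.slope == pytest.approx(oracle.slope, rel=1e-12)
        assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-9)
        assert res.n == 4

    def test_stage_window_respected(self):
        specs = [self._spec(f"s{j}", d, p) for j, (d, p) in
                 enumerate([(1, 1.0), (2, 1.0), (3, 1.0), (11, 0.5), (12, 0.4)])]
        res = pyl_stasis_test(specs, (0, 10))
        assert res.n == 3 and res.slope == 0.0

    def test_zero_noise_simulation_has_zero_slope(self, zero_noise_specs):
        res = pyl_stasis_test(zero_noise_specs, (0, 10))
        assert res.slope == 0.0 and res.p_value == 1.0

    def test_single_stage_is_error(self):
        specs = [self._spec(f"s{j}", 4, 0.5 + 0.01 * j) for j in range(5)]
        with pytest.raises(ValueError):
            pyl_stasis_test(specs, (0, 10))

    def test_too_few_specimens_is_error(self):
        with pytest.raises(ValueError):
            pyl_stasis_test([self._spec("a", 1, 0.5)], (0, 10))
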