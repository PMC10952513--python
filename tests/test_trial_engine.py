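"""Trial engine: escalation bookkeeping, allocation, stopping rules, final test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import logit

from duocomb import (DesignConfig, DoseCombination, MTDCurve, SamplerSettings,
                     StandardizedDensity, ToxParams, TrialDesign, TrialResult,
                     final_test, futility_stop, sample_doses_rejection,
                     stage2_safety_stop)
from duocomb.doses import mtd_x_solution, mtd_y_solution
from duocomb.records import to_frame
from duocomb.trial import DECISIONS

from conftest import make_records, point_mass_tox_results, synthetic_eff_results


class TestDesignConfig:
    def test_sample_size_bookkeeping(self):
        cfg = DesignConfig()
        assert cfg.N1 == cfg.C1 * cfg.m1 == 30
        assert cfg.N2 == cfg.n2 + cfg.C2 * cfg.m2 == 30

    def test_feasibility_bound_schedule(self):
        cfg = DesignConfig()
        # cohort 1 fixed start; from cohort 2 the bound grows by 0.05/cohort
        assert cfg.ewoc_alpha(1) == 0.25
        assert cfg.ewoc_alpha(2) == 0.25
        assert cfg.ewoc_alpha(3) == pytest.approx(0.30)
        assert cfg.ewoc_alpha(7) == pytest.approx(0.50)
        assert cfg.ewoc_alpha(12) == 0.50  # capped

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(delta_0=0.5, delta_u=0.4)
        with pytest.raises(ValueError):
            DesignConfig(theta_T=1.5)
        with pytest.raises(ValueError):
            DesignConfig(omega=1.2)

    def test_round_trip_dict(self):
        cfg = DesignConfig(omega=0.25, C1=4, m1=3)
        back = DesignConfig.from_dict(cfg.to_dict())
        assert back == cfg


class TestStage1Escalation:
    """The dose-assignment pattern of the escalation algorithm, isolated from
    MCMC by patching the toxicity fit with a point-mass posterior at the
    true parameters."""

    @pytest.fixture
    def traced(self, tox_params_1, monkeypatch):
        from duocomb import toxicity

        def fake_fit(self, **kwargs):
            return point_mass_tox_results(tox_params_1)

        monkeypatch.setattr(toxicity.ToxicityModel, "fit", fake_fit)
        cfg = DesignConfig(C1=3, C2=1, n2=2, m2=2)
        design = TrialDesign(cfg)
        rng = np.random.default_rng(0)
        records, post, log, _ = design.run_stage1(lambda d, s, r: (0, 1), rng)
        return cfg, to_frame(records), tox_params_1

    def test_cohort1_is_the_start_dose(self, traced):
        cfg, df, params = traced
        assert tuple(df.loc[0, ["x_std", "y_std"]]) == cfg.start_dose
        assert tuple(df.loc[1, ["x_std", "y_std"]]) == cfg.start_dose

    def test_cohort2_conditions_on_start_doses(self, traced):
        cfg, df, params = traced
        theta = cfg.theta_T
        # patient 3: new x given y1; patient 4: new y given x2 (alpha = 0.25
        # percentile of a point mass is the deterministic conditional MTD)
        x3 = np.clip(mtd_x_solution(0.5, params, theta), 0, 1)
        y4 = np.clip(mtd_y_solution(0.33, params, theta), 0, 1)
        assert df.loc[2, "x_std"] == pytest.approx(float(x3), abs=1e-12)
        assert df.loc[2, "y_std"] == 0.5
        assert df.loc[3, "x_std"] == 0.33
        assert df.loc[3, "y_std"] == pytest.approx(float(y4), abs=1e-12)

    def test_cohort3_alternates_the_conditioning_pattern(self, traced):
        cfg, df, params = traced
        theta = cfg.theta_T
        # odd cohort: patient 5 keeps patient 3's x and gets a new y;
        # patient 6 keeps patient 4's y and gets a new x
        x3, y4 = df.loc[2, "x_std"], df.loc[3, "y_std"]
        y5 = np.clip(mtd_y_solution(x3, params, theta), 0, 1)
        x6 = np.clip(mtd_x_solution(y4, params, theta), 0, 1)
        assert df.loc[4, "x_std"] == x3
        assert df.loc[4, "y_std"] == pytest.approx(float(y5), abs=1e-12)
        assert df.loc[5, "x_std"] == pytest.approx(float(x6), abs=1e-12)
        assert df.loc[5, "y_std"] == y4

    def test_safety_stop_terminates_stage1(self, monkeypatch):
        from duocomb import toxicity

        toxic = ToxParams(rho00=0.6, rho01=0.65, rho10=0.65, alpha3=0.1)

        def fake_fit(self, **kwargs):
            return point_mass_tox_results(toxic)

        monkeypatch.setattr(toxicity.ToxicityModel, "fit", fake_fit)
        design = TrialDesign(DesignConfig())
        records, post, log, _ = design.run_stage1(
            lambda d, s, r: (1, 0), np.random.default_rng(0))
        assert post is None
        assert len(records) == 2  # stopped after the first cohort
        result = design.run(lambda d, s, r: (1, 0), seed=1)
        assert result.decision == "stopped_safety_s1"


class TestStandardizedDensity:
    def test_constant_curve_gives_uniform_density(self):
        dens = StandardizedDensity(lambda x: np.full_like(np.asarray(x, float), 0.3),
                                   (0.2, 0.8))
        assert dens.integral() == pytest.approx(1.0, abs=1e-6)
        assert dens.pdf(0.5) == pytest.approx(1.0 / 0.6, abs=1e-9)

    def test_linear_ramp_normalizes_to_closed_form(self):
        # pi(x) = 0.1 + x on [0,1]: normalizer 0.6, CDF (0.1 x + x^2/2)/0.6
        dens = StandardizedDensity(lambda x: 0.1 + np.asarray(x, float), (0.0, 1.0))
        assert dens.integral() == pytest.approx(1.0, abs=1e-6)
        for x in (0.25, 0.5, 0.9):
            assert dens.pdf(x) == pytest.approx((0.1 + x) / 0.6, abs=1e-6)
            assert dens.cdf(x) == pytest.approx((0.1 * x + x ** 2 / 2) / 0.6, abs=1e-5)

    def test_nonpositive_curve_rejected(self):
        with pytest.raises(ValueError):
            StandardizedDensity(lambda x: np.asarray(x, float) - 0.5, (0.0, 1.0))


class TestRejectionSampler:
    def test_uniform_density_passes_ks(self, curve_1):
        lo, hi = curve_1.x_domain
        dens = StandardizedDensity(lambda x: np.ones_like(np.asarray(x, float)),
                                   (lo, hi))
        rng = np.random.default_rng(14)
        doses = sample_doses_rejection(dens, curve_1, 10000, rng)
        xs = (np.array([d.x for d in doses]) - lo) / (hi - lo)
        ks = stats.kstest(xs, "uniform")
        assert ks.statistic < 1.63 / np.sqrt(len(xs))  # 1% critical value

    def test_ramp_density_matches_analytic_cdf(self, curve_1):
        lo, hi = curve_1.x_domain
        dens = StandardizedDensity(lambda x: (np.asarray(x, float) - lo) / (hi - lo) + 1e-9,
                                   (lo, hi))
        rng = np.random.default_rng(15)
        doses = sample_doses_rejection(dens, curve_1, 10000, rng)
        u = (np.array([d.x for d in doses]) - lo) / (hi - lo)
        ks = stats.kstest(u, lambda t: t ** 2)
        assert ks.statistic < 1.63 / np.sqrt(len(u))

    def test_sampled_points_lie_on_the_curve(self, curve_1):
        lo, hi = curve_1.x_domain
        dens = StandardizedDensity(lambda x: np.ones_like(np.asarray(x, float)),
                                   (lo, hi))
        doses = sample_doses_rejection(dens, curve_1, 200, np.random.default_rng(16))
        for d in doses:
            assert curve_1.tox_params.prob_dlt(d.x, d.y) == pytest.approx(0.33, abs=1e-8)


class TestStoppingRules:
    def test_futility_triggers_when_nothing_is_promising(self, curve_1):
        rows = np.tile([logit(0.01), -3.0, -3.0, 0.0], (200, 1))
        res = synthetic_eff_results(rows)
        cfg = DesignConfig()
        assert futility_stop(res, curve_1, cfg) is True

    def test_single_promising_point_prevents_futility(self, curve_1):
        # half the draws put high efficacy everywhere: exceedance 0.5 > 0.1
        rows = np.vstack([np.tile([logit(0.9), 0.0, 0.0, 0.0], (100, 1)),
                          np.tile([logit(0.01), -3.0, -3.0, 0.0], (100, 1))])
        res = synthetic_eff_results(rows)
        assert futility_stop(res, curve_1, DesignConfig()) is False

    def test_futility_threshold_counting_oracle(self, curve_1):
        # 8% of draws promising -> max exceedance 0.08 < delta_0 = 0.1
        rows = np.vstack([np.tile([logit(0.9), 0.0, 0.0, 0.0], (8, 1)),
                          np.tile([logit(0.001), -4.0, -4.0, 0.0], (92, 1))])
        res = synthetic_eff_results(rows)
        assert futility_stop(res, curve_1, DesignConfig()) is True

    def test_stage2_safety_closed_form_matches_quadrature(self):
        cfg = DesignConfig()
        k, n = 20, 40
        df = make_records(np.zeros(n), np.zeros(n),
                          np.r_[np.ones(k), np.zeros(n - k)].astype(int))
        # closed-form Beta survival vs numeric integration of the density
        a, b = 0.5 + k, 0.5 + n - k
        num, _ = quad(lambda t: stats.beta.pdf(t, a, b), cfg.theta_T + 0.1, 1.0,
                      epsabs=1e-14)
        assert stats.beta.sf(cfg.theta_T + 0.1, a, b) == pytest.approx(num, abs=1e-10)
        expected = stats.beta.sf(cfg.theta_T + 0.1, a, b) > cfg.delta_theta2
        assert stage2_safety_stop(df, cfg) is bool(expected)

    def test_stage2_safety_extremes(self):
        cfg = DesignConfig()
        no_dlt = make_records(np.zeros(10), np.zeros(10), np.zeros(10, int))
        assert stage2_safety_stop(no_dlt, cfg) is False
        all_dlt = make_records(np.zeros(10), np.zeros(10), np.ones(10, int))
        assert stage2_safety_stop(all_dlt, cfg) is True

    def test_stage2_safety_can_restrict_to_stage2(self):
        cfg = DesignConfig(stage2_safety_pooled=False)
        s1 = make_records(np.zeros(10), np.zeros(10), np.ones(10, int), stage=1)
        assert stage2_safety_stop(s1, cfg) is False


class TestFinalTest:
    def test_uniform_exceedance_below_delta_u_accepts(self, curve_1):
        # 39% of draws uniformly promising -> exceedance 0.39 < 0.4 everywhere
        rows = np.vstack([np.tile([logit(0.99), 0.0, 0.0, 0.0], (39, 1)),
                          np.tile([logit(0.001), -4.0, -4.0, 0.0], (61, 1))])
        res = synthetic_eff_results(rows)
        reject, _, mx = final_test(res, curve_1, DesignConfig())
        assert mx == pytest.approx(0.39, abs=1e-12)
        assert reject is False

    def test_x_driven_surface_rejects_at_high_x_end(self, curve_1):
        # X-driven surface with intercept spread: the exceedance profile is
        # strictly increasing in x, so the argmax is the curve's right end
        rng = np.random.default_rng(4)
        rows = np.column_stack([rng.normal(-7.0, 2.0, 400),
                                np.full(400, np.log(10.0)),
                                np.full(400, -3.0), np.zeros(400)])
        res = synthetic_eff_results(rows)
        cfg = DesignConfig()
        reject, opt, mx = final_test(res, curve_1, cfg)
        assert reject is True
        pts = curve_1.equally_spaced_points(cfg.grid_size)
        # at the right end up to tie-breaking (equal exceedance -> lowest x)
        assert opt.x >= pts[-3].x
        assert mx == pytest.approx(res.prob_eff_exceeds(opt, 0.15), abs=1e-12)

    def test_argmax_matches_fine_grid_oracle(self, curve_1):
        rng = np.random.default_rng(8)
        rows = np.column_stack([rng.normal(-2, 0.7, 400), rng.normal(1, 0.3, 400),
                                rng.normal(1, 0.3, 400), rng.gamma(2, 2, 400)])
        res = synthetic_eff_results(rows)
        cfg = DesignConfig(grid_size=101)
        _, opt, _ = final_test(res, cfg_curve := curve_1, cfg)
        fine = curve_1.equally_spaced_points(1001)
        exc = res.exceedance_profile(fine, cfg.p0)
        best = fine[int(np.argmax(exc))]
        # within one coarse grid step of the fine-grid argmax
        step = curve_1.total_arc_length() / (cfg.grid_size - 1)
        d = np.hypot(opt.x - best.x, opt.y - best.y)
        assert d <= step + 1e-9

    def test_raising_delta_u_only_removes_rejections(self, curve_1):
        rng = np.random.default_rng(12)
        rows = np.column_stack([rng.normal(-1.5, 1, 300), rng.normal(0, 0.5, 300),
                                rng.normal(0, 0.5, 300), rng.gamma(1, 2, 300)])
        res = synthetic_eff_results(rows)
        rejections = []
        for du in (0.2, 0.4, 0.6, 0.8):
            cfg = DesignConfig(delta_u=du)
            rejections.append(final_test(res, curve_1, cfg)[0])
        # once a rejection turns off it stays off
        assert all(a >= b for a, b in zip(rejections, rejections[1:]))


class TestFullTrial:
    def test_completed_trial_bookkeeping(self, scenario_h1_ca, sim_config):
        res = TrialDesign(sim_config).run(scenario_h1_ca, seed=202)
        assert res.decision in DECISIONS
        if res.decision in ("reject_h0", "accept_h0"):
            assert res.n_enrolled == sim_config.N1 + sim_config.N2
        s2 = res.records[res.records["stage"] == 2]
        curve = res.curve
        for _, row in s2.iterrows():
            pi = curve.tox_params.prob_dlt(row["x_std"], row["y_std"])
            assert pi == pytest.approx(curve.theta_T, abs=1e-6)
        # the run-in cohort is equally spaced along the curve
        run_in = s2[s2["cohort"] == 0]
        assert len(run_in) == sim_config.n2

    def test_no_tolerable_set_flagged(self, monkeypatch):
        from duocomb import toxicity

        # posterior believes even the lowest combination is above target
        hot = ToxParams(rho00=0.42, rho01=0.5, rho10=0.5, alpha3=0.1)

        def fake_fit(self, **kwargs):
            return point_mass_tox_results(hot)

        monkeypatch.setattr(toxicity.ToxicityModel, "fit", fake_fit)
        cfg = DesignConfig(delta_theta1=0.99)  # disable the stage-1 stop
        res = TrialDesign(cfg).run(lambda d, s, r: (0, 0), seed=5)
        assert res.decision == "no_tolerable_set"
        assert res.optimal_dose is None
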