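"""Generator reproducibility, null embedding and oracle correctness."""

import numpy as np
import pandas as pd
import pytest

from unmask import (
    ColliderSimConfig,
    ConfigError,
    DoseResponseSimConfig,
    SequentialSimConfig,
    VaccineSimConfig,
    simulate_collider,
    simulate_dose_response,
    simulate_sequential,
    simulate_vaccine,
)
from unmask.simulators import REGIMES

SIMS = [
    (simulate_collider, ColliderSimConfig(n=300, seed=5)),
    (simulate_vaccine, VaccineSimConfig(n_per_arm=100, T_weeks=4, seed=5)),
    (simulate_dose_response, DoseResponseSimConfig(n=300, seed=5)),
    (simulate_sequential, SequentialSimConfig(n=300, seed=5)),
]


@pytest.mark.parametrize("fn,cfg", SIMS, ids=lambda v: getattr(v, "__name__", ""))
def test_identical_config_and_seed_reproduce_bit_identical_data(fn, cfg):
    d1, _ = fn(cfg)
    d2, _ = fn(cfg)
    pd.testing.assert_frame_equal(d1.df, d2.df)


def test_growing_n_preserves_earlier_subjects():
    small, _ = simulate_collider(ColliderSimConfig(n=100, seed=9))
    large, _ = simulate_collider(ColliderSimConfig(n=200, seed=9))
    pd.testing.assert_frame_equal(large.df.iloc[:100], small.df)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        ColliderSimConfig(n=0).validate()
    with pytest.raises(ConfigError):
        VaccineSimConfig(p_exposure=1.5).validate()
    with pytest.raises(ConfigError):
        VaccineSimConfig(rho_feedback=0.0).validate()
    with pytest.raises(ConfigError):
        DoseResponseSimConfig(alpha_d=0.5).validate()  # P(E=1|d=3) > 1
    with pytest.raises(ConfigError):
        SequentialSimConfig(carryover_decay=0.0).validate()


class TestCollider:
    def test_null_dgp_drives_truths_to_zero(self):
        cfg = ColliderSimConfig(n=50, beta_A=0.0, kappa_A=0.0, seed=0)
        _, truth = simulate_collider(cfg)
        assert truth.true_ATE == 0.0
        assert truth.true_CDE[1] == 0.0
        for b in (0, 1):
            assert truth.extras["stratified_truth"][b] == pytest.approx(0.0, abs=1e-10)

    def test_no_collider_path_when_trait_ignores_belief(self):
        cfg = ColliderSimConfig(n=50, kappa_U=0.0, seed=0)
        _, truth = simulate_collider(cfg)
        for b in (0, 1):
            assert truth.extras["stratified_truth"][b] == pytest.approx(
                cfg.beta_A, abs=1e-8
            )

    def test_default_sign_flip_certified_by_numeric_integration(self):
        # the headline collider-bias reversal: beneficial direct effect but
        # harmful-looking within-belief contrast, independent of sampling
        cfg = ColliderSimConfig(n=1)
        _, truth = simulate_collider(cfg)
        assert truth.true_CDE[1] < 0
        assert truth.extras["stratified_truth"][1] > 0
        assert truth.extras["rebalanced_truth"] > 0
        assert truth.method == "numeric_integration"


class TestVaccine:
    def test_cumulative_infections_nondecreasing_per_subject(self):
        data, _ = simulate_vaccine(VaccineSimConfig(n_per_arm=200, T_weeks=6, seed=1))
        wide = data.df.pivot(index="subject_id", columns="week",
                             values="cum_infections")
        assert (wide.diff(axis=1).iloc[:, 1:] >= 0).all().all()

    def test_zero_efficacy_gives_identical_arm_trajectories(self):
        cfg = VaccineSimConfig(n_per_arm=100, vaccine_efficacy=0.0,
                               feedback_enabled=False, seed=2,
                               oracle_mc_reps=2000)
        _, truth = simulate_vaccine(cfg)
        np.testing.assert_array_equal(
            truth.extras["expected_cumulative_a1"],
            truth.extras["expected_cumulative_a0"],
        )

    def test_identity_feedback_equals_feedback_disabled(self):
        kw = dict(n_per_arm=150, T_weeks=6, seed=3, oracle_mc_reps=500)
        d_rho1, _ = simulate_vaccine(VaccineSimConfig(rho_feedback=1.0, **kw))
        d_off, _ = simulate_vaccine(
            VaccineSimConfig(feedback_enabled=False, **kw)
        )
        pd.testing.assert_frame_equal(d_rho1.df, d_off.df)

    def test_feedback_shrinks_between_arm_gap_in_oracle(self):
        kw = dict(n_per_arm=10, seed=4, oracle_mc_reps=30_000)
        _, t_on = simulate_vaccine(VaccineSimConfig(feedback_enabled=True, **kw))
        _, t_off = simulate_vaccine(VaccineSimConfig(feedback_enabled=False, **kw))
        assert t_on.extras["final_week_gap"] < t_off.extras["final_week_gap"]
        # the per-exposure mechanism itself is untouched by feedback
        assert (
            t_on.extras["per_exposure_risk_ratio"]
            == t_off.extras["per_exposure_risk_ratio"]
            == 0.5
        )


class TestDoseResponse:
    def test_full_mediation_closed_form(self):
        cfg = DoseResponseSimConfig(gamma_d=0.0, gamma_E=5.0, alpha_d=0.2)
        _, truth = simulate_dose_response(cfg)
        assert all(v == 0.0 for v in truth.true_CDE.values())
        assert truth.extras["naive_trend_per_level"] == pytest.approx(1.0)

    def test_expectancy_blinded_naive_trend_equals_cde_slope(self):
        cfg = DoseResponseSimConfig(alpha_d=0.0, gamma_d=1.0)
        _, truth = simulate_dose_response(cfg)
        assert truth.extras["naive_trend_per_level"] == pytest.approx(
            truth.extras["cde_slope_per_level"]
        )

    def test_closed_form_verified_by_large_sample_means(self):
        cfg = DoseResponseSimConfig(n=100_000, gamma_d=1.0, gamma_E=2.0,
                                    alpha_d=0.15, seed=6)
        data, truth = simulate_dose_response(cfg)
        # naive per-level trend = gamma_d + gamma_E * alpha_d = 1.3
        assert truth.extras["naive_trend_per_level"] == pytest.approx(1.3)
        d, y = data.A, data.Y
        slope = np.polyfit(d, y, 1)[0]
        assert slope == pytest.approx(1.3, abs=0.05)
        # CDE slope: within fixed E, regression on dose recovers gamma_d
        m = data.E == 1
        slope_e = np.polyfit(d[m], y[m], 1)[0]
        assert slope_e == pytest.approx(1.0, abs=0.08)


class TestSequential:
    def test_all_sixteen_regimes_enumerated(self):
        assert len(REGIMES) == 16
        _, truth = simulate_sequential(SequentialSimConfig(n=10, seed=0,
                                                           oracle_mc_reps=100))
        assert set(truth.regime_means) == set(REGIMES)

    def test_null_dgp_equalizes_all_regime_means_exactly(self):
        cfg = SequentialSimConfig(
            n=10, message_effect=0.0, treatment_effect=0.0,
            expectancy_effect=0.0, feedback_strength=0.0,
            treatment_on_expectancy=0.0, seed=1, oracle_mc_reps=5000,
        )
        _, truth = simulate_sequential(cfg)
        vals = np.array(list(truth.regime_means.values()))
        assert np.ptp(vals) == 0.0  # common random numbers: exactly equal

    def test_perfect_durability_makes_early_late_contrast_zero(self):
        # with full carryover and no treatment->expectancy or feedback path,
        # treating early vs late yields the same final outcome
        cfg = SequentialSimConfig(
            n=10, carryover_decay=1.0, treatment_on_expectancy=0.0,
            feedback_strength=0.0, seed=2, oracle_mc_reps=5000,
        )
        _, truth = simulate_sequential(cfg)
        early = truth.regime_means[((1, 0), (0, 0))]
        late = truth.regime_means[((0, 0), (1, 0))]
        assert early == pytest.approx(late, abs=1e-12)

    def test_sample_regime_mean_matches_counterfactual_oracle(self):
        cfg = SequentialSimConfig(n=8000, seed=3)
        ldata, truth = simulate_sequential(cfg)
        twice = ((1, 0), (1, 0))
        once = ((1, 0), (0, 0))
        regs = ldata.regimes()["regime"]
        y2 = ldata.wide("Y")[2]
        diffs = []
        for reg in (twice, once):
            sel = regs == reg
            diffs.append(y2[sel].mean())
            assert sel.sum() > 100
        observed = diffs[0] - diffs[1]
        oracle = truth.regime_means[twice] - truth.regime_means[once]
        # each regime holds ~ n/16 subjects
        se = np.sqrt(sum(y2[regs == r].var() / (regs == r).sum()
                         for r in (twice, once)))
        assert abs(observed - oracle) < 3 * se
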