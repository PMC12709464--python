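"""Estimator correctness against oracles, algebraic identities and the
bias demonstrations."""

import numpy as np
import pandas as pd
import pytest

import unmask
from unmask import (
    ColliderSimConfig,
    DoseResponseSimConfig,
    EstimandSpec,
    LearnerSpec,
    SequentialSimConfig,
    TrialDataset,
    TrialSchema,
    estimate_ate,
    estimate_cde_dr,
    estimate_cde_gcomp,
    estimate_cde_ipw,
    estimate_msm,
    estimate_rebalanced_naive,
    estimate_stratified_naive,
    estimate_tfcde,
    fit_nuisances,
    simulate_collider,
    simulate_dose_response,
    simulate_sequential,
)
from unmask.estimators import EstimationError

from conftest import MILD_COLLIDER, make_discrete_dataset

CDE_SPEC = EstimandSpec(kind="CDE", a1=1, a0=0, e=1)
SAT = LearnerSpec(family="saturated", n_folds=1)


def _trivial_data(Y, A=None, E=None, n=None):
    n = n or len(Y)
    A = A if A is not None else np.arange(n) % 2
    E = E if E is not None else np.arange(n) // (n // 2 or 1) % 2
    df = pd.DataFrame({"A": A, "E": E, "Y": Y})
    return TrialDataset(df, TrialSchema(treatment="A", expectancy="E", outcome="Y"))


class TestATE:
    def test_outcome_equal_treatment_gives_unit_effect(self):
        A = np.array([0, 1, 0, 1, 0, 1])
        data = _trivial_data(Y=A.astype(float), A=A)
        assert estimate_ate(data).point == 1.0

    def test_constant_outcome_gives_zero(self):
        data = _trivial_data(Y=np.full(6, 3.3))
        est = estimate_ate(data)
        assert est.point == 0.0
        assert est.se == pytest.approx(0.0, abs=1e-12)

    def test_empty_arm_raises(self):
        data = _trivial_data(Y=np.ones(4), A=np.ones(4, dtype=int))
        with pytest.raises(EstimationError, match="A=0"):
            estimate_ate(data)

    def test_matches_numeric_integration_oracle(self, collider_draw):
        data, truth = collider_draw
        est = estimate_ate(data)
        assert abs(est.point - truth.true_ATE) < 3 * est.se


class TestStratifiedNaive:
    def test_no_collider_path_agrees_with_ate(self):
        data, truth = simulate_collider(
            ColliderSimConfig(n=20_000, kappa_U=0.0, seed=1)
        )
        ate = estimate_ate(data)
        with pytest.warns(UserWarning, match="BIASED_DEMO"):
            strat = estimate_stratified_naive(data, "belief")
        for est in strat.values():
            assert abs(est.point - ate.point) < 3 * np.hypot(est.se, ate.se)

    def test_single_stratum_reduces_to_ate(self):
        data, _ = simulate_collider(
            ColliderSimConfig(n=2000, kappa_0=50.0, seed=2)  # belief always 1
        )
        assert set(np.unique(data.B)) == {1.0}
        with pytest.warns(UserWarning):
            strat = estimate_stratified_naive(data, "belief")
        assert strat[1.0].point == estimate_ate(data).point

    def test_default_world_reverses_sign_within_belief(self, collider_draw):
        data, truth = collider_draw
        with pytest.warns(UserWarning):
            strat = estimate_stratified_naive(data, "belief")
        assert truth.true_CDE[1] < 0
        assert truth.extras["stratified_truth"][1] > 0
        assert strat[1.0].point > 0  # the estimate reproduces the reversal


class TestRebalancedNaive:
    def test_identical_expectancy_distributions_reduce_to_ate(self):
        # equal (A, E) cell counts: every rebalancing weight is exactly 1
        A = np.repeat([0, 1], 8)
        E = np.tile([0, 0, 0, 1, 1, 1, 1, 1], 2)
        Y = np.arange(16.0)
        data = _trivial_data(Y=Y, A=A, E=E)
        with pytest.warns(UserWarning):
            reb = estimate_rebalanced_naive(data)
        assert reb.point == estimate_ate(data).point

    def test_zero_effect_dgp_is_null(self):
        data, _ = simulate_collider(ColliderSimConfig(
            n=20_000, beta_A=0.0, beta_U=0.0, kappa_A=0.0, seed=3
        ))
        with pytest.warns(UserWarning):
            reb = estimate_rebalanced_naive(data)
        assert abs(reb.point) < 3 * reb.se

    def test_sign_reversal_against_closed_form_truth(self, collider_draw):
        data, truth = collider_draw
        with pytest.warns(UserWarning):
            reb = estimate_rebalanced_naive(data)
        assert truth.true_CDE[1] < 0 < truth.extras["rebalanced_truth"]
        assert reb.point > 0
        assert abs(reb.point - truth.extras["rebalanced_truth"]) < 5 * reb.se

    def test_missing_cell_raises(self):
        A = np.repeat([0, 1], 4)
        E = np.array([0, 0, 0, 0, 0, 1, 1, 1])  # no control mass at E=1
        with pytest.warns(UserWarning):
            with pytest.raises(EstimationError, match="E=1"):
                estimate_rebalanced_naive(_trivial_data(np.ones(8), A=A, E=E))


class TestCDEEngines:
    def test_triple_agreement_and_brute_force_on_saturated_data(self, discrete_data):
        data = discrete_data
        nuis = fit_nuisances(data, CDE_SPEC, SAT, delta=0.0)
        g = estimate_cde_gcomp(data, CDE_SPEC, nuisances=nuis, n_boot=0)
        i = estimate_cde_ipw(data, CDE_SPEC, nuisances=nuis, hajek=False, n_boot=0)
        d = estimate_cde_dr(data, CDE_SPEC, nuisances=nuis)
        assert abs(g.point - i.point) < 1e-10
        assert abs(g.point - d.point) < 1e-10
        # brute-force double summation of the g-formula
        X, Z, A, E, Y = (data.X[:, 0], data.Z[:, 0], data.A, data.E, data.Y)

        def psi(a):
            tot = 0.0
            for x in (0, 1):
                arm = (X == x) & (A == a)
                inner = 0.0
                for z in (0, 1):
                    fz = np.sum(arm & (Z == z)) / arm.sum()
                    inner += fz * Y[arm & (Z == z) & (E == 1)].mean()
                tot += np.mean(X == x) * inner
            return tot

        assert g.point == pytest.approx(psi(1) - psi(0), abs=1e-10)

    def test_randomized_everything_ipw_equals_cell_mean_difference(self):
        data = make_discrete_dataset(n=500, seed=8)
        nuis = fit_nuisances(
            data, CDE_SPEC, LearnerSpec(family="saturated", n_folds=1),
            known_treatment_probs=0.5, delta=0.0,
        ).replace_pi_e(0.5)
        est = estimate_cde_ipw(data, CDE_SPEC, nuisances=nuis, hajek=True, n_boot=0)
        m = data.E == 1
        cell_diff = (data.Y[m & (data.A == 1)].mean()
                     - data.Y[m & (data.A == 0)].mean())
        assert est.point == pytest.approx(cell_diff, abs=1e-12)

    def test_mediator_inert_cde_reduces_to_ate(self):
        # belief/expectancy and the trait have no outcome effect
        data, _ = simulate_collider(ColliderSimConfig(n=10_000, beta_U=0.0, seed=9))
        ate = estimate_ate(data)
        cde = estimate_cde_dr(data, CDE_SPEC,
                              learners=LearnerSpec(family="linear", n_folds=2),
                              known_treatment_probs=0.5)
        assert abs(cde.point - ate.point) < 3 * np.hypot(cde.se, ate.se)

    def test_full_mediation_cde_null_while_ate_is_not(self):
        cfg = DoseResponseSimConfig(n=10_000, gamma_d=0.0, dose_levels=(0, 1),
                                    alpha_d=0.3, seed=10)
        data, truth = simulate_dose_response(cfg)
        ate = estimate_ate(data)
        assert ate.point - 3 * ate.se > 0  # naive contrast bounded away from 0
        cde = estimate_cde_dr(
            data, CDE_SPEC, learners=LearnerSpec(family="linear", n_folds=2),
            known_treatment_probs={0.0: 0.5, 1.0: 0.5},
        )
        assert abs(cde.point) < 3 * cde.se

    def test_dr_robust_to_single_nuisance_misspecification(self):
        cfg = ColliderSimConfig(n=10_000, seed=12, **MILD_COLLIDER)
        data, truth = simulate_collider(cfg)
        L = LearnerSpec(family="linear", n_folds=5)
        nuis = fit_nuisances(data, CDE_SPEC, L, known_treatment_probs=0.5, seed=1)
        dr_wrong_pi = estimate_cde_dr(data, CDE_SPEC,
                                      nuisances=nuis.replace_pi_e(0.5))
        assert abs(dr_wrong_pi.point - truth.true_CDE[1]) < 3 * dr_wrong_pi.se
        bad_mu = LearnerSpec(family="linear", n_folds=5, mu_features=("X",))
        nuis_b = fit_nuisances(data, CDE_SPEC, bad_mu,
                               known_treatment_probs=0.5, seed=1)
        g_wrong = estimate_cde_gcomp(data, CDE_SPEC, nuisances=nuis_b, n_boot=0)
        dr_wrong_mu = estimate_cde_dr(data, CDE_SPEC, nuisances=nuis_b)
        assert abs(g_wrong.point - truth.true_CDE[1]) > 1.0  # gcomp is off
        assert abs(dr_wrong_mu.point - truth.true_CDE[1]) < 3 * dr_wrong_mu.se

    def test_bootstrap_se_is_reasonable(self):
        cfg = ColliderSimConfig(n=1500, seed=13, **MILD_COLLIDER)
        data, truth = simulate_collider(cfg)
        est = estimate_cde_gcomp(
            data, CDE_SPEC, learners=LearnerSpec(family="linear", n_folds=2),
            known_treatment_probs=0.5, n_boot=60, seed=0,
        )
        assert est.se > 0
        assert abs(est.point - truth.true_CDE[1]) < 4 * est.se


class TestTfCDE:
    def test_equal_levels_give_exact_zero(self, discrete_data):
        spec = EstimandSpec(kind="tfCDE", a=1, e1=1, e0=1)
        est = estimate_tfcde(discrete_data, spec)
        assert est.point == 0.0 and est.se == 0.0

    def test_null_expectancy_effect(self):
        cfg = DoseResponseSimConfig(n=10_000, gamma_E=0.0, seed=14)
        data, _ = simulate_dose_response(cfg)
        spec = EstimandSpec(kind="tfCDE", a=1, e1=1, e0=0)
        known = {float(d): 0.25 for d in cfg.dose_levels}
        est = estimate_tfcde(data, spec,
                             learners=LearnerSpec(family="linear", n_folds=2),
                             known_treatment_probs=known)
        assert abs(est.point) < 3 * est.se

    @pytest.mark.parametrize("engine", ["gcomp", "ipw", "dr"])
    def test_matches_closed_form_truth(self, engine):
        cfg = DoseResponseSimConfig(n=10_000, seed=15)
        data, truth = simulate_dose_response(cfg)
        spec = EstimandSpec(kind="tfCDE", a=2, e1=1, e0=0)
        known = {float(d): 0.25 for d in cfg.dose_levels}
        est = estimate_tfcde(
            data, spec, learners=LearnerSpec(family="linear", n_folds=2),
            known_treatment_probs=known, engine=engine, n_boot=40,
        )
        target = truth.true_tfCDE[(2, (1, 0))]
        assert abs(est.point - target) < 3.5 * max(est.se, 0.05)


class TestMSM:
    def test_marginal_randomization_weights_are_unit_and_contrast_raw(self):
        ldata, _ = simulate_sequential(SequentialSimConfig(n=1500, seed=16))
        w = unmask.compute_msm_weights(
            ldata, randomized_probs={"treatment": 0.5, "message": 0.5}
        )
        assert np.all(w.weights == 1.0)
        r1, r0 = ((1, 1), (1, 1)), ((0, 0), (0, 0))
        est = estimate_msm(ldata, r1, r0, w)
        regs = ldata.regimes()["regime"]
        y2 = ldata.wide("Y")[2]
        raw = y2[regs == r1].mean() - y2[regs == r0].mean()
        assert est.point == pytest.approx(raw, abs=1e-12)

    def test_fitted_weights_near_unit_under_marginal_randomization(self):
        ldata, _ = simulate_sequential(SequentialSimConfig(n=3000, seed=17))
        w = unmask.compute_msm_weights(ldata)
        assert abs(w.weights.mean() - 1.0) < 0.05
        assert w.effective_sample_size > 0.9 * ldata.n_subjects

    def test_null_dgp_regime_means_indistinguishable(self):
        cfg = SequentialSimConfig(
            n=2000, message_effect=0.0, treatment_effect=0.0,
            expectancy_effect=0.0, feedback_strength=0.0,
            treatment_on_expectancy=0.0, seed=18, oracle_mc_reps=1000,
        )
        ldata, _ = simulate_sequential(cfg)
        w = unmask.compute_msm_weights(
            ldata, randomized_probs={"treatment": 0.5, "message": 0.5}
        )
        base = ((0, 0), (0, 0))
        from unmask.simulators import REGIMES

        for reg in REGIMES:
            if reg == base:
                continue
            est = estimate_msm(ldata, reg, base, w)
            assert abs(est.point) < 3.5 * est.se

    def test_contrast_matches_counterfactual_oracle(self):
        ldata, truth = simulate_sequential(SequentialSimConfig(n=4000, seed=19))
        w = unmask.compute_msm_weights(
            ldata, randomized_probs={"treatment": 0.5, "message": 0.5}
        )
        twice, once = ((1, 0), (1, 0)), ((1, 0), (0, 0))
        est = estimate_msm(ldata, twice, once, w)
        oracle = truth.regime_means[twice] - truth.regime_means[once]
        assert abs(est.point - oracle) < 3 * est.se

    def test_unmatched_regime_raises_positivity_error(self):
        ldata, _ = simulate_sequential(SequentialSimConfig(n=50, seed=20))
        df = ldata.df.copy()
        df.loc[df["t"] == 1, "A"] = 0  # no subject ever treated at t=1
        ldata2 = unmask.LongitudinalDataset(df, ldata.schema)
        with pytest.raises(EstimationError, match="positivity"):
            estimate_msm(ldata2, ((1, 0), (1, 0)), ((0, 0), (0, 0)),
                         unmask.compute_msm_weights(
                             ldata2, randomized_probs={"treatment": 0.5,
                                                       "message": 0.5}))


class TestFlattenedSequentialCDE:
    def test_final_period_cde_and_tfcde_match_structural_truth(self):
        cfg = SequentialSimConfig(n=8000, seed=21)
        ldata, truth = simulate_sequential(cfg)
        flat = unmask.flatten_two_period(ldata)
        L = LearnerSpec(family="linear", n_folds=2)
        cde = estimate_cde_dr(flat, CDE_SPEC, learners=L,
                              known_treatment_probs=0.5)
        assert abs(cde.point - truth.true_CDE[1]) < 3 * cde.se
        tf = estimate_tfcde(
            flat, EstimandSpec(kind="tfCDE", a=1, e1=1, e0=0),
            learners=L, known_treatment_probs=0.5,
        )
        assert abs(tf.point - truth.true_tfCDE[(1, (1, 0))]) < 3 * tf.se
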