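import numpy as np
import pandas as pd
import pytest

from tcirc import (
    ErrorModel,
    NoiseSpec,
    ParameterSet,
    apply_omega_scaling,
    endogenous_steady_state,
    fit_stage1_endogenous,
    fit_stage2_exogenous,
    log_likelihood,
    make_kinetic_dataset,
    make_steady_state_dataset,
    make_thymectomy_dataset,
    relative_standard_errors,
    weighted_residuals,
)
from tcirc.calibrate import FitResult, fit_ml, predictions


def _exact_dataset(params, cv=0.2):
    """Steady-state dataset whose values equal the model medians exactly."""
    return make_steady_state_dataset(params, NoiseSpec(cv=1e-12, seed=0)).assign(cv=cv)


def _manual_fit(params, data, error=ErrorModel(), free=("mu13",)):
    return FitResult(params=params, estimates={n: getattr(params, n) for n in free},
                     free=tuple(free), loglik=0.0, data=data, error=error,
                     fixed={}, converged=True, n_starts=0)


class TestLogLikelihood:
    def test_exact_predictions_attain_maximal_value(self, params):
        """With zero log-residuals LL equals sum of -log(y*sigma*sqrt(2pi))."""
        data = _exact_dataset(params)
        sigma = np.sqrt(np.log1p(0.2 ** 2))
        y = data["value"].to_numpy()
        expected = np.sum(-np.log(y * sigma * np.sqrt(2 * np.pi)))
        assert log_likelihood(params, data) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_independent_records(self, params):
        data = make_steady_state_dataset(params, NoiseSpec(cv=0.2, seed=3))
        double = pd.concat([data, data], ignore_index=True)
        assert log_likelihood(params, double) == pytest.approx(2 * log_likelihood(params, data))

    def test_invariant_to_record_order(self, params):
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=4))
        shuffled = data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        assert log_likelihood(params, shuffled) == pytest.approx(log_likelihood(params, data))

    def test_zero_prediction_raises(self, params):
        """A blocked route (mu16ex=0) makes the regional-LN prediction zero,
        where the log-normal density is undefined."""
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=0))
        with pytest.raises(ValueError, match="log-normal"):
            log_likelihood(params.replace(mu16ex=0.0), data)

    def test_truth_beats_perturbed_truth_in_replicates(self, params):
        """Monte-Carlo: LL at the generating parameters exceeds LL with
        mu13 halved in >= 95% of 100 seeded replicates."""
        worse = params.replace(mu13=params.mu13 / 2)
        wins = 0
        for seed in range(100):
            data = make_steady_state_dataset(params, NoiseSpec(cv=0.2, seed=seed))
            wins += log_likelihood(params, data) > log_likelihood(worse, data)
        assert wins >= 95


class TestStage1:
    def test_zero_noise_optimum_is_at_truth(self, params):
        """Starting at the truth on noise-free data, the optimizer cannot
        improve on the generating parameters."""
        data = _exact_dataset(params, cv=0.05)
        fit = fit_stage1_endogenous(data, params, n_starts=1, seed=0)
        ll_truth = log_likelihood(params, data)
        assert fit.loglik >= ll_truth - 1e-6
        assert fit.estimates["mu13"] == pytest.approx(params.mu13, rel=1e-3)

    def test_consistency_bias_shrinks_with_noise(self, params):
        """Median |log error| of mu13 decreases as cv drops 20% -> 1%."""
        errs = {}
        for cv in (0.2, 0.01):
            e = []
            for seed in range(5):
                data = make_steady_state_dataset(params, NoiseSpec(cv=cv, seed=seed))
                fit = fit_stage1_endogenous(data, params, n_starts=2, seed=seed)
                e.append(abs(np.log(fit.estimates["mu13"] / params.mu13)))
            errs[cv] = np.median(e)
        assert errs[0.01] < errs[0.2]
        assert errs[0.01] < 0.05

    def test_afferent_penalty_pulls_fraction_toward_target(self, params):
        from tcirc.calibrate import _afferent_fraction
        data = make_steady_state_dataset(params, NoiseSpec(cv=0.2, seed=1))
        free = ("mu25", "mu45")
        loose = fit_ml(data, params, free, n_starts=1, seed=0)
        tight = fit_ml(data, params, free, n_starts=1, seed=0,
                       afferent_penalty_weight=1e4, afferent_target=0.10)
        assert abs(_afferent_fraction(tight.params) - 0.10) <= \
            abs(_afferent_fraction(loose.params) - 0.10) + 1e-9


class TestStage2:
    def test_lymphoid_delay_tie_enforced(self, params):
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=2))
        fit = fit_stage2_exogenous(data, params, n_starts=1, seed=0)
        assert fit.params.kdel5 == fit.params.kdel3
        assert fit.params.kdel6 == fit.params.kdel3

    def test_endogenous_steady_state_frozen(self, params):
        """Stage 2 must not move the endogenous equilibrium."""
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=2))
        before = endogenous_steady_state(params)
        fit = fit_stage2_exogenous(data, params, n_starts=1, seed=0)
        after = endogenous_steady_state(fit.params)
        assert np.allclose(before, after, rtol=1e-12)

    def test_liver_delay_retention_recovered(self, params):
        """The fitted liver delay inflow stays large relative to its exit
        rate (strong liver retention, as in the published fit)."""
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=11))
        fit = fit_stage2_exogenous(data, params, n_starts=2, seed=11)
        assert fit.estimates["kdel4"] / fit.params.koff4 > 10

    def test_no_delay_signature_hits_lower_bound(self, params):
        """Data generated without any delay kinetics drive kdel3 to the
        box boundary, which is flagged."""
        truth = params.replace(kdel3=0.0, kdel5=0.0, kdel6=0.0, kdel4=0.0)
        data = make_kinetic_dataset(truth, noise=NoiseSpec(cv=0.1, seed=5))
        fit = fit_stage2_exogenous(data, params, n_starts=1, seed=0, bounds_fold=100.0)
        assert "kdel3" in fit.at_bounds or "kdel4" in fit.at_bounds


class TestRSE:
    def test_matches_analytic_single_parameter_oracle(self, params):
        """One log-linear parameter, n replicate observations, fixed sigma:
        the information is n/sigma^2, so RSE = 100*sigma/sqrt(n)."""
        p = params.replace(Vmax_pro=0.0)  # blood steady state = Vinf/k_apo
        pred = endogenous_steady_state(p)[0] / p.physiology.V_blood
        n, sigma = 25, 0.2
        data = pd.DataFrame({
            "organ": "blood", "population": "endogenous",
            "protocol": "steady-state", "time_h": np.nan,
            "value": np.full(n, pred), "unit": "cells_per_ml",
            "cv": 0.2, "dose": np.nan, "omega": 1.0,
        })
        fit = _manual_fit(p, data, ErrorModel(sigma=sigma), free=("V_inf_thymus",))
        rse = relative_standard_errors(fit)
        assert rse["V_inf_thymus"] == pytest.approx(100 * sigma / np.sqrt(n), rel=1e-3)

    def test_rse_shrinks_with_noise(self, params):
        p = params.replace(Vmax_pro=0.0)
        pred = endogenous_steady_state(p)[0] / p.physiology.V_blood
        def rse_at(sigma):
            data = pd.DataFrame({
                "organ": "blood", "population": "endogenous",
                "protocol": "steady-state", "time_h": np.nan,
                "value": np.full(25, pred), "unit": "cells_per_ml",
                "cv": 0.2, "dose": np.nan, "omega": 1.0,
            })
            fit = _manual_fit(p, data, ErrorModel(sigma=sigma), free=("V_inf_thymus",))
            return relative_standard_errors(fit)["V_inf_thymus"]
        assert rse_at(0.02) == pytest.approx(rse_at(0.2) / 10, rel=1e-2)


class TestWRES:
    def test_zero_at_expectation(self, params):
        sigma = np.sqrt(np.log1p(0.2 ** 2))
        data = _exact_dataset(params)
        data["value"] *= np.exp(sigma ** 2 / 2)  # shift medians to the means
        fit = _manual_fit(params, data, ErrorModel(sigma=sigma))
        assert np.allclose(weighted_residuals(fit), 0.0, atol=1e-9)

    def test_self_consistency_mean_and_variance(self, params):
        """WRES of data simulated from the model: mean ~0, variance ~1."""
        frames = [make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=s))
                  for s in range(3)]  # 120 records
        data = pd.concat(frames, ignore_index=True)
        fit = _manual_fit(params, data)
        w = weighted_residuals(fit)
        assert abs(w.mean()) < 0.15
        assert abs(w.var(ddof=1) - 1.0) < 0.3

    def test_simulation_based_expectation_agrees_with_analytic(self, params):
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=9))
        fit = _manual_fit(params, data)
        wa = weighted_residuals(fit, method="analytic")
        ws = weighted_residuals(fit, method="simulation", n_sim=20000, seed=0)
        assert np.allclose(wa, ws, atol=0.08)


class TestOmegaScaling:
    def test_identity_and_example(self, params):
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=0))
        same = apply_omega_scaling(data, 1.0)
        assert np.allclose(same["value"], data["value"])
        one = data.iloc[[0]].assign(value=1.0e6)
        assert apply_omega_scaling(one, 2.7)["value"].iloc[0] == pytest.approx(2.7e6)

    def test_inverse_round_trip_and_provenance(self, params):
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=0))
        back = apply_omega_scaling(apply_omega_scaling(data, 2.7), 1 / 2.7)
        assert np.allclose(back["value"], data["value"], rtol=1e-12)
        scaled = apply_omega_scaling(data, 2.7)
        assert np.allclose(scaled["omega"], 2.7)

    def test_nonpositive_omega_rejected(self, params):
        data = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=0))
        with pytest.raises(ValueError):
            apply_omega_scaling(data, 0.0)


class TestThymectomyRecovery:
    def test_vmax_recovered_from_decay_series(self, params):
        """The decay after thymic ablation identifies Vmax_pro."""
        data = make_thymectomy_dataset(params, NoiseSpec(cv=0.1, seed=3))
        fit = fit_ml(data, params, free=("Vmax_pro",), n_starts=2, seed=3)
        assert fit.estimates["Vmax_pro"] == pytest.approx(params.Vmax_pro, rel=0.4)


class TestPredictions:
    def test_units_must_be_cells_per_ml(self, params):
        from tcirc.synthetic import AssaySpec
        df = make_kinetic_dataset(params, noise=NoiseSpec(cv=0.2, seed=0),
                                  assay=AssaySpec(unit="counts_per_gram"))
        with pytest.raises(ValueError, match="cells/ml"):
            predictions(params, df)
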