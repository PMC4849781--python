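import numpy as np
import pytest

from conftest import CHAIN3_FAST_SCHEDULE, CHAIN3_SCHEDULE, chain3_problem
from tracekin.experiments import Condition, Observable
from tracekin.fitting import AnnealSchedule, FitProblem, FitResult, fit_anneal, objective
from tracekin.identifiability import chi2_threshold, envelopes, profile_parameter
from tracekin.models import generate_synthetic_dataset, make_toy


class TestChi2Threshold:
    def test_95_percent_one_df(self):
        assert chi2_threshold(0.05) == pytest.approx(3.841, abs=1e-3)

    def test_one_sigma_rule(self):
        assert chi2_threshold(0.32) == pytest.approx(0.989, abs=0.01)

    def test_monotone_in_significance(self):
        assert chi2_threshold(0.01) > chi2_threshold(0.05) > chi2_threshold(0.5)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 2.0])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            chi2_threshold(alpha)


DEGEN_CONDITION = Condition("d", t_end=120.0)
DEGEN_OBS = [Observable("C", "conc")]


def degenerate_problem(seed=21):
    model = make_toy("degenerate_pair")
    ds = generate_synthetic_dataset(model, [DEGEN_CONDITION], DEGEN_OBS,
                                    noise_sd=0.01, seed=seed,
                                    times=(30.0, 60.0, 120.0))
    return FitProblem(model, [DEGEN_CONDITION], ds)


class TestDegeneratePair:
    def test_profile_flat_under_brute_force_reoptimization(self):
        # raising the fast downstream capacity and re-optimizing the other
        # factor on a brute-force grid never exceeds the 95% threshold:
        # the profile of k2 is flat upward
        from scipy.optimize import minimize_scalar

        prob = degenerate_problem()
        base = objective(np.array([1.0, 1.0]), prob)
        for k2 in (3.0, 10.0, 30.0, 100.0):
            r = minimize_scalar(
                lambda k1: objective(np.array([k1, k2]), prob),
                bounds=(0.5, 2.0), method="bounded",
                options={"xatol": 1e-6},
            )
            assert r.fun - base < chi2_threshold(0.05)

    def test_profile_reports_unbounded_interval(self):
        prob = degenerate_problem()
        sched = AnnealSchedule(t0=5.0, cooling=0.7,
                               moves_per_temperature=15,
                               t_min_ratio=1e-6, max_evaluations=500,
                               move_scale=0.3)
        fit = fit_anneal(prob, sched, seed=3, store_predictions=False)
        prof = profile_parameter(prob, fit, "k2", alpha=0.05,
                                 bound_ratio=100.0, seed=1)
        assert not prof.upper_bounded


@pytest.fixture(scope="module")
def fitted():
    prob = chain3_problem(0.01, seed=31)
    fit = fit_anneal(prob, CHAIN3_SCHEDULE, seed=8,
                     x0=np.array([0.5, 2.0, 0.8]),
                     store_predictions=False)
    return prob, fit


class TestChain3Profiles:

    def test_identifiable_interval_contains_truth(self, fitted):
        prob, fit = fitted
        prof = profile_parameter(prob, fit, "k2", alpha=0.05, seed=2,
                                 reopt_budget_fraction=0.05)
        assert prof.identifiable
        assert prof.contains(1.0)
        assert prof.lower < prof.best_value < prof.upper

    def test_profile_minimum_at_best_fit(self, fitted):
        prob, fit = fitted
        prof = profile_parameter(prob, fit, "k1", alpha=0.05, seed=2,
                                 reopt_budget_fraction=0.05)
        chi2s = [c for _, c in prof.profile_points if np.isfinite(c)]
        assert fit.chi2 <= min(chi2s) + 1e-9


class TestEnvelopes:
    def _problem_and_fit(self):
        prob = chain3_problem(0.01, seed=41)
        fit = FitResult(np.ones(3), prob.factor_names,
                        objective(np.ones(3), prob), 1, 0)
        return prob, fit

    def test_no_profiles_collapses_to_best_fit(self):
        prob, fit = self._problem_and_fit()
        bands = envelopes(prob, fit, [], prob.conditions[0], ["B", "C"])
        for b in bands:
            assert np.allclose(b.lower, b.best)
            assert np.allclose(b.upper, b.best)

    def test_band_contains_best_fit_and_widens_monotonically(self):
        prob, fit = self._problem_and_fit()
        from tracekin.identifiability import ProfileResult

        p1 = ProfileResult("k1", 1.0, 0.8, 1.2, 0.05, 3.84,
                           accepted_sets=[np.array([1.1, 1.0, 1.0])])
        p2 = ProfileResult("k2", 1.0, 0.8, 1.2, 0.05, 3.84,
                           accepted_sets=[np.array([1.0, 0.85, 1.0])])
        small = envelopes(prob, fit, [p1], prob.conditions[0], ["C"])[0]
        big = envelopes(prob, fit, [p1, p2], prob.conditions[0], ["C"])[0]
        assert np.all(small.lower <= small.best + 1e-12)
        assert np.all(small.best <= small.upper + 1e-12)
        assert np.all(big.lower <= small.lower + 1e-12)
        assert np.all(big.upper >= small.upper - 1e-12)

    def test_flux_and_mid_variables_supported(self):
        prob, fit = self._problem_and_fit()
        bands = envelopes(prob, fit, [], prob.conditions[0],
                          ["flux:r2", Observable("B", "mid", None, 2)])
        names = {b.variable for b in bands}
        assert "flux:r2" in names and "B:C*:m2" in names
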