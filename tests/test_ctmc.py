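import math

import numpy as np
import pytest
from scipy import stats as sps

from dyadstate.ctmc import (
    PERMITTED_EDGES,
    FitResult,
    IntensityModel,
    closed_form_intensities,
    fit_mle,
    holm_adjust,
    log_likelihood,
    wald_test_coefficient,
    wald_test_intensity_contrast,
)
from dyadstate.eventlog import PairTrajectory, TransitionEvent
from dyadstate.metrics import sufficient_statistics
from dyadstate.simulate import build_pair_model, simulate_trajectory

from conftest import make_trajectory


@pytest.fixture
def two_exit_model():
    return IntensityModel(baseline={(1, 2): 0.1, (1, 3): 0.05})


class TestLogLikelihood:
    def test_single_sojourn_closed_form(self, two_exit_model):
        t = make_trajectory([(10.0, (1, 2))], duration=10.0000001)
        # -(0.15)(10) + ln 0.1, final sojourn term is ~0 (state 2 absorbing here)
        ll = log_likelihood(two_exit_model, t)
        assert ll == pytest.approx(-1.5 + math.log(0.1), abs=1e-6)
        assert ll == pytest.approx(-3.802585, abs=1e-5)

    def test_pure_censoring_term(self):
        model = IntensityModel(baseline={(1, 2): 0.015, (1, 3): 0.005})
        t = make_trajectory([], duration=100.0)
        assert log_likelihood(model, t) == pytest.approx(-2.0)

    def test_covariate_substitution_oracle(self, two_exit_model):
        # independent oracle: effect of satiated=1 with beta12 = ln 2 must equal
        # a covariate-free model with q12 doubled
        model = IntensityModel(
            baseline={(1, 2): 0.1, (1, 3): 0.05},
            effects={"satiated": {(1, 2): math.log(2.0)}},
        )
        doubled = IntensityModel(baseline={(1, 2): 0.2, (1, 3): 0.05})
        t = make_trajectory([(10.0, (1, 2)), (30.0, (2, 1))], duration=50.0)
        with pytest.raises(Exception):
            # model references the covariate; it must be supplied
            log_likelihood(model, t, {})
        assert log_likelihood(model, t, {"satiated": 1.0}) == pytest.approx(
            log_likelihood(doubled, t), abs=1e-12
        )

    def test_likelihood_additive_over_trajectories(self):
        model = build_pair_model(0.4, 0.3)
        t1 = simulate_trajectory(model, {"satiated": 0}, 500.0, seed=1)
        t2 = simulate_trajectory(model, {"satiated": 0}, 500.0, seed=2)
        fit = fit_mle([t1, t2])
        ll = sum(log_likelihood(fit.estimates, t) for t in (t1, t2))
        assert fit.log_lik == pytest.approx(ll, rel=1e-9)


class TestClosedForm:
    def test_direct_ratio(self):
        t = make_trajectory(
            [(float(k), (1, 2) if k % 2 else (2, 1)) for k in range(1, 11)],
            duration=100.0,
        )
        stats = sufficient_statistics(t)
        est = closed_form_intensities(stats)
        assert est[(1, 2)] == pytest.approx(stats.counts[(1, 2)] / stats.sojourn[1])

    def test_unvisited_state_flagged(self):
        t = make_trajectory([], duration=100.0)
        est = closed_form_intensities(sufficient_statistics(t))
        assert est[(3, 4)] is None  # state 3 never visited
        assert est[(1, 2)] == 0.0

    def test_inconsistent_stats_rejected(self):
        stats = sufficient_statistics(make_trajectory([], duration=10.0))
        stats.counts[(3, 4)] = 2  # events without sojourn
        with pytest.raises(ValueError, match="inconsistent"):
            closed_form_intensities(stats)

    def test_matches_numerical_mle(self, rng):
        model = build_pair_model(0.5, 0.35)
        t = simulate_trajectory(model, {"satiated": 0}, duration=30000.0, seed=rng)
        crude = closed_form_intensities(sufficient_statistics(t))
        fit = fit_mle([t])
        for e in PERMITTED_EDGES:
            assert fit.estimates.baseline[e] == pytest.approx(crude[e], rel=1e-6)


class TestFitMle:
    def test_unidentifiable_coefficient_flagged(self):
        # edge 2->4 never occurs under satiated=1
        model = build_pair_model(0.5, 0.35)
        control = simulate_trajectory(model, {"satiated": 0}, 4000.0, seed=3)
        satiated = make_trajectory([], duration=4000.0, session="satiated")
        fit = fit_mle(
            [control, satiated],
            [{"satiated": 0}, {"satiated": 1}],
            design={"satiated": PERMITTED_EDGES},
        )
        assert ("satiated", (2, 4)) in fit.unidentifiable
        assert not fit.is_identifiable("satiated", (2, 4))
        # baselines estimated from control data are unaffected
        crude = closed_form_intensities(sufficient_statistics(control))
        # satiated session adds sojourn in state 1 only
        assert fit.estimates.baseline[(2, 4)] == pytest.approx(crude[(2, 4)], rel=1e-6)
        with pytest.raises(ValueError, match="unidentifiable"):
            wald_test_coefficient(fit, "satiated", (2, 4))

    def test_degenerate_edge_floored(self):
        t = make_trajectory([(5.0, (1, 2)), (15.0, (2, 1))], duration=100.0)
        fit = fit_mle([t])
        assert (3, 4) in fit.degenerate_edges
        assert fit.estimates.baseline[(3, 4)] == pytest.approx(1e-8)
        assert fit.converged

    def test_recovers_known_beta(self):
        model = build_pair_model(0.45, 0.45)
        trajs, covs = [], []
        for k in range(30):
            for satiated in (0, 1):
                trajs.append(
                    simulate_trajectory(
                        model, {"satiated": satiated}, 7200.0, seed=1000 + 2 * k + satiated
                    )
                )
                covs.append({"satiated": satiated})
        fit = fit_mle(trajs, covs, design={"satiated": PERMITTED_EDGES})
        assert fit.converged
        assert fit.estimate_working("satiated", (1, 2)) == pytest.approx(-1.0, abs=0.15)
        assert fit.estimate_working("satiated", (3, 4)) == pytest.approx(-1.0, abs=0.15)
        assert fit.estimate_working("satiated", (1, 3)) == pytest.approx(0.0, abs=0.15)

    def test_mle_beats_perturbations(self, rng):
        model = build_pair_model(0.5, 0.3)
        trajs = [
            simulate_trajectory(model, {"satiated": 0}, 3000.0, seed=rng)
            for _ in range(4)
        ]
        fit = fit_mle(trajs)
        best = sum(log_likelihood(fit.estimates, t) for t in trajs)
        for _ in range(100):
            jitter = {
                e: q * math.exp(rng.normal(0, 0.05))
                for e, q in fit.estimates.baseline.items()
            }
            perturbed = IntensityModel(baseline=jitter)
            ll = sum(log_likelihood(perturbed, t) for t in trajs)
            assert ll <= best + 1e-9

    def test_time_scaling_invariance(self):
        model = build_pair_model(0.5, 0.3)
        t = simulate_trajectory(model, {"satiated": 0}, 5000.0, seed=9)
        fit = fit_mle([t])
        c = 3.0
        scaled = PairTrajectory(
            pair_id=t.pair_id,
            session=t.session,
            duration=t.duration * c,
            initial_state=t.initial_state,
            events=[
                TransitionEvent(time=e.time * c, from_state=e.from_state, to_state=e.to_state)
                for e in t.events
            ],
        )
        fit_scaled = fit_mle([scaled])
        for e in PERMITTED_EDGES:
            if e in fit.degenerate_edges:
                continue
            assert fit_scaled.estimates.baseline[e] * c == pytest.approx(
                fit.estimates.baseline[e], rel=1e-8
            )

    def test_ci_brackets_estimate(self):
        model = build_pair_model(0.5, 0.3)
        t = simulate_trajectory(model, {"satiated": 0}, 20000.0, seed=4)
        fit = fit_mle([t])
        for e in PERMITTED_EDGES:
            if e in fit.degenerate_edges:
                continue
            lo, hi = fit.ci95("baseline", e)
            assert 0 < lo < fit.estimates.baseline[e] < hi

    def test_consistency_with_duration(self):
        # median absolute error of log q12 shrinks with observation time
        model = build_pair_model(0.5, 0.35)
        true_q12 = model.baseline[(1, 2)]
        errors = []
        for duration in (2000.0, 20000.0, 200000.0):
            errs = []
            for k in range(15):
                t = simulate_trajectory(
                    model, {"satiated": 0}, duration, seed=50 + k
                )
                fit = fit_mle([t])
                errs.append(abs(math.log(fit.estimates.baseline[(1, 2)] / true_q12)))
            errors.append(np.median(errs))
        assert errors[0] > errors[1] > errors[2]


class TestWaldTests:
    def _fit_with_cov(self):
        model = build_pair_model(0.5, 0.5)
        trajs, covs = [], []
        for k in range(6):
            for s in (0, 1):
                trajs.append(simulate_trajectory(model, {"satiated": s}, 3600.0, seed=70 + 2 * k + s))
                covs.append({"satiated": s})
        return fit_mle(trajs, covs, design={"satiated": PERMITTED_EDGES})

    def test_zero_estimate_gives_p_one(self):
        fit = self._fit_with_cov()
        est = fit.estimate_working("satiated", (1, 2))
        res = wald_test_coefficient(fit, "satiated", (1, 2), null_value=est)
        assert res.z == 0.0 and res.p == 1.0

    def test_normal_tail_oracle(self):
        fit = self._fit_with_cov()
        est = fit.estimate_working("satiated", (1, 2))
        se = fit.se_working("satiated", (1, 2))
        res = wald_test_coefficient(fit, "satiated", (1, 2), null_value=est + 2.0 * se)
        assert res.z == pytest.approx(-2.0)
        assert res.p == pytest.approx(0.0455, abs=2e-4)
        assert res.p == pytest.approx(2 * sps.norm.sf(2.0), rel=1e-12)
        assert res.direction == -1

    def test_contrast_equal_rates(self):
        # symmetric boldness: q12 and q13 estimates close; z matches hand formula
        fit = self._fit_with_cov()
        res = wald_test_intensity_contrast(fit, (1, 2), (1, 3))
        ia = fit.params.index(("baseline", (1, 2)))
        ib = fit.params.index(("baseline", (1, 3)))
        d = fit.working[ia] - fit.working[ib]
        var = fit.cov[ia, ia] + fit.cov[ib, ib] - 2 * fit.cov[ia, ib]
        assert res.z == pytest.approx(d / math.sqrt(var), rel=1e-12)
        assert res.p == pytest.approx(2 * sps.norm.sf(abs(res.z)), rel=1e-12)

    def test_contrast_delta_method_hand_value(self):
        # independent log-estimates, difference 1.0, SEs 0.3 and 0.4 -> z = 2
        var = 0.3**2 + 0.4**2
        z = 1.0 / math.sqrt(var)
        assert z == pytest.approx(2.0)
        assert 2 * sps.norm.sf(z) == pytest.approx(0.0455, abs=1e-4)

    def test_holm_adjustment(self):
        adj = holm_adjust([0.01, 0.04, 0.03, 0.005])
        assert adj == pytest.approx([0.03, 0.06, 0.06, 0.02])
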