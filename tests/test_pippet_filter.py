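import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pippet import (
    EventStream,
    ExpectationTemplate,
    FilterConfig,
    GaussianBelief1D,
    GaussianPeak,
    between_event_derivative,
    candidate_posterior,
    event_update,
    hazards,
    make_isochronous_template,
    plan_next_tap,
    run_mpippet,
    run_pippet,
)
from pippet.generative import metronome

from .conftest import oracle_moments_1d, random_template


class TestCandidatePosterior:
    def test_symmetry(self):
        peak = GaussianPeak(phi=0.5, v=0.01, lam=1.0)
        for V in (0.001, 0.01, 1.0):
            mu_hat, _ = candidate_posterior(GaussianBelief1D(mu=0.5, V=V), peak)
            assert mu_hat == pytest.approx(0.5)

    def test_uninformative_prior_limit(self):
        peak = GaussianPeak(phi=0.5, v=0.01, lam=1.0)
        mu_hat, V_hat = candidate_posterior(GaussianBelief1D(mu=-3.0, V=1e12), peak)
        assert mu_hat == pytest.approx(0.5, abs=1e-6)
        assert V_hat == pytest.approx(0.01, rel=1e-9)

    def test_precision_weighted_mean(self):
        # equal precisions: posterior mean is halfway, variance halves
        peak = GaussianPeak(phi=0.5, v=0.01, lam=1.0)
        mu_hat, V_hat = candidate_posterior(GaussianBelief1D(mu=0.4, V=0.01), peak)
        assert mu_hat == pytest.approx(0.45)
        assert V_hat == pytest.approx(0.005)


class TestHazards:
    def test_near_degenerate_prior(self):
        t = ExpectationTemplate(lambda_0=0.0, peaks=(GaussianPeak(0.5, 0.01, 1.0),))
        h = hazards(GaussianBelief1D(mu=0.4, V=1e-12), t)
        assert h.Lambda_total == pytest.approx(2.419707245191434, rel=1e-6)

    def test_no_peaks(self):
        h = hazards(GaussianBelief1D(mu=0.0, V=0.01), ExpectationTemplate(lambda_0=0.7))
        assert h.Lambda_total == 0.7
        assert h.per_peak == ()

    def test_convolved_hazard_value(self):
        # frozen: Lambda_1 = 2 * N(0.3; 0.5, 0.01 + 0.04), total adds lambda_0
        t = ExpectationTemplate(lambda_0=0.5, peaks=(GaussianPeak(0.5, 0.01, 2.0),))
        h = hazards(GaussianBelief1D(mu=0.3, V=0.04), t)
        assert h.per_peak[0][0] == pytest.approx(2.3918683193456394, rel=1e-12)
        assert h.Lambda_total == pytest.approx(2.8918683193456394, rel=1e-12)

    def test_weights_normalize(self):
        t = ExpectationTemplate(
            lambda_0=0.3,
            peaks=(GaussianPeak(0.2, 0.004, 1.0), GaussianPeak(0.7, 0.01, 2.0)),
        )
        h = hazards(GaussianBelief1D(mu=0.4, V=0.02), t)
        weights = h.Lambda_0 / h.Lambda_total + sum(
            L / h.Lambda_total for L, _, _ in h.per_peak
        )
        assert weights == pytest.approx(1.0, rel=1e-15)


class TestEventUpdate:
    def test_single_peak_at_mean(self):
        t = ExpectationTemplate(lambda_0=0.0, peaks=(GaussianPeak(0.5, 0.01, 1.0),))
        post = event_update(GaussianBelief1D(mu=0.5, V=0.02), t)
        assert post.mu == pytest.approx(0.5)
        assert post.V == pytest.approx(1.0 / (1 / 0.02 + 1 / 0.01))

    def test_far_event_attributed_to_background(self):
        t = ExpectationTemplate(lambda_0=0.5, peaks=(GaussianPeak(5.0, 0.0004, 1.0),))
        prior = GaussianBelief1D(mu=0.0, V=0.001)
        post = event_update(prior, t)
        assert post.mu == pytest.approx(prior.mu, abs=1e-9)
        assert post.V == pytest.approx(prior.V, rel=1e-6)

    def test_liminal_event_inflates_variance(self):
        # background cause vs a moderately distant peak: causal ambiguity
        t = ExpectationTemplate(lambda_0=0.5, peaks=(GaussianPeak(0.5, 0.0004, 1.0),))
        prior = GaussianBelief1D(mu=0.35, V=0.002)
        post = event_update(prior, t)
        assert post.V > prior.V

    def test_zero_hazard_raises(self):
        t = ExpectationTemplate(lambda_0=0.0, peaks=(GaussianPeak(5.0, 0.0001, 1.0),))
        with pytest.raises(ValueError, match="lambda_0"):
            event_update(GaussianBelief1D(mu=0.0, V=0.0001), t)

    def test_matches_quadrature_oracle(self, rng):
        for _ in range(25):
            t = random_template(rng)
            mu = float(rng.uniform(-1, 1))
            V = float(rng.uniform(0.001, 0.1))
            post = event_update(GaussianBelief1D(mu=mu, V=V), t)
            m, v, _ = oracle_moments_1d(mu, V, t)
            assert post.mu == pytest.approx(m, rel=1e-8, abs=1e-8)
            assert post.V == pytest.approx(v, rel=1e-8)

    @given(
        mu=st.floats(-1, 1),
        V=st.floats(0.001, 0.1),
        phi=st.floats(-1, 1),
        v=st.floats(0.001, 0.05),
        lam=st.floats(0.1, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_single_peak_correction_fraction(self, mu, V, phi, v, lam):
        # lambda_0 = 0, one peak: (mu+ - mu)/(phi - mu) = V/(V + v),
        # independent of lam
        t = ExpectationTemplate(lambda_0=0.0, peaks=(GaussianPeak(phi, v, lam),))
        if abs(mu - phi) > 6 * math.sqrt(v + V):
            return  # hazard numerically zero: update undefined by design
        post = event_update(GaussianBelief1D(mu=mu, V=V), t)
        if abs(phi - mu) > 1e-9:
            frac = (post.mu - mu) / (phi - mu)
            assert frac == pytest.approx(V / (V + v), rel=1e-9)
        assert post.V == pytest.approx(1.0 / (1 / V + 1 / v), rel=1e-9)
        assert post.V < V

    def test_correction_grows_with_peak_strength_when_background(self):
        # with lambda_0 > 0 the correction magnitude is monotone in lam_1
        prior = GaussianBelief1D(mu=0.35, V=0.002)
        corrections = []
        for lam in (0.2, 0.5, 1.0, 2.0, 5.0):
            t = ExpectationTemplate(
                lambda_0=0.5, peaks=(GaussianPeak(0.5, 0.0025, lam),)
            )
            post = event_update(prior, t)
            corrections.append(post.mu - prior.mu)
        assert all(c > 0 for c in corrections)
        assert corrections == sorted(corrections)


class TestBetweenEventDerivative:
    def test_pure_drift(self):
        t = ExpectationTemplate(lambda_0=0.0, peaks=(GaussianPeak(50.0, 0.001, 1.0),))
        dmu, dV = between_event_derivative(
            GaussianBelief1D(mu=0.0, V=0.01), t, sigma=0.2
        )
        assert dmu == 1.0
        assert dV == pytest.approx(0.04)

    def test_phase_drags_before_expected_event(self):
        t = ExpectationTemplate(lambda_0=0.01, peaks=(GaussianPeak(0.5, 0.001, 2.0),))
        dmu, _ = between_event_derivative(
            GaussianBelief1D(mu=0.42, V=0.005), t, sigma=0.1
        )
        assert dmu < 1.0

    def test_no_event_push_opposes_event_update(self):
        t = ExpectationTemplate(lambda_0=0.01, peaks=(GaussianPeak(0.5, 0.001, 2.0),))
        belief = GaussianBelief1D(mu=0.42, V=0.005)
        dmu, _ = between_event_derivative(belief, t, sigma=0.0)
        post = event_update(belief, t)
        assert (post.mu - belief.mu) * (dmu - 1.0) < 0


class TestRunPippet:
    def test_background_only_closed_form(self):
        cfg = FilterConfig(dt=0.001, sigma=0.2, mu0=0.3, V0=0.01, t_end=2.0)
        traj = run_pippet(
            ExpectationTemplate(lambda_0=0.5), EventStream(times=np.array([])), cfg
        )
        np.testing.assert_allclose(traj.mu, 0.3 + traj.times, atol=1e-10)
        np.testing.assert_allclose(traj.V, 0.01 + 0.04 * traj.times, rtol=1e-12)

    def test_zero_strength_peaks_match_closed_form(self):
        cfg = FilterConfig(dt=0.001, sigma=0.15, mu0=0.0, V0=0.001, t_end=1.5)
        t = make_isochronous_template(0.5, 4, strength=0.0, variance=0.001, lambda_0=0.4)
        traj = run_pippet(t, EventStream(times=np.array([])), cfg)
        np.testing.assert_allclose(traj.mu, traj.times, atol=1e-10)
        np.testing.assert_allclose(traj.V, 0.001 + 0.15**2 * traj.times, rtol=1e-12)

    def test_events_contract_variance(self):
        t = make_isochronous_template(0.5, 6, strength=1.0, variance=0.0004, lambda_0=0.01)
        cfg = FilterConfig(dt=0.001, sigma=0.1, t_end=2.6)
        traj = run_pippet(t, metronome(0.5, 5, start=0.5), cfg)
        for k in traj.event_marks:
            assert traj.V[k] < traj.V[k - 1]

    def test_event_outside_window_rejected(self):
        cfg = FilterConfig(dt=0.001, t_end=1.0)
        with pytest.raises(ValueError, match="window"):
            run_pippet(
                ExpectationTemplate(lambda_0=0.5),
                EventStream(times=np.array([2.0])),
                cfg,
            )

    def test_grid_refinement_stability(self):
        t = make_isochronous_template(0.5, 6, strength=0.5, variance=0.001, lambda_0=0.05)
        events = metronome(0.5, 4, start=0.5)
        finals = []
        for dt in (0.001, 0.0005):
            cfg = FilterConfig(dt=dt, sigma=0.08, t_end=2.2)
            traj = run_pippet(t, events, cfg)
            finals.append((traj.mu[-1], traj.V[-1]))
        assert abs(finals[0][0] - finals[1][0]) < 1e-3
        assert abs(finals[0][1] - finals[1][1]) < 1e-3

    def test_trajectory_shapes(self):
        cfg = FilterConfig(dt=0.01, t_end=1.0)
        traj = run_pippet(
            ExpectationTemplate(lambda_0=0.5),
            EventStream(times=np.array([0.5])),
            cfg,
        )
        assert traj.times.size == 101
        assert traj.mu.size == traj.V.size == traj.Lambda.size == 101
        assert list(traj.event_marks) == [50]
        assert np.all(traj.V > 0)


class TestRunMpippet:
    def test_single_stream_reduces_to_pippet(self):
        t = make_isochronous_template(0.5, 5, strength=0.8, variance=0.001, lambda_0=0.02)
        events = metronome(0.5, 4, start=0.5)
        cfg = FilterConfig(dt=0.001, sigma=0.1, t_end=2.2)
        t1 = run_pippet(t, events, cfg)
        t2 = run_mpippet(
            {"a": t}, EventStream(events.times, labels=("a",) * 4), cfg
        )
        np.testing.assert_array_equal(t1.mu, t2.mu)
        np.testing.assert_array_equal(t1.V, t2.V)

    def test_two_stream_drift_additivity(self):
        # disjoint-peak streams: total no-event drift correction equals the
        # sum of the per-stream corrections computed independently
        ta = ExpectationTemplate(lambda_0=0.05, peaks=(GaussianPeak(0.5, 0.002, 1.0),))
        tb = ExpectationTemplate(lambda_0=0.02, peaks=(GaussianPeak(0.8, 0.004, 2.0),))
        belief = GaussianBelief1D(mu=0.45, V=0.01)
        da, _ = between_event_derivative(belief, ta, sigma=0.0)
        db, _ = between_event_derivative(belief, tb, sigma=0.0)
        cfg = FilterConfig(dt=0.001, sigma=0.0, mu0=belief.mu, V0=belief.V, t_end=0.001)
        traj = run_mpippet(
            {"a": ta, "b": tb}, EventStream(np.array([]), labels=()), cfg
        )
        dmu_total = (traj.mu[1] - traj.mu[0]) / cfg.dt
        assert dmu_total == pytest.approx((da - 1.0) + (db - 1.0) + 1.0, rel=1e-9)

    def test_unlabelled_events_rejected_with_multiple_templates(self):
        t = ExpectationTemplate(lambda_0=0.5)
        cfg = FilterConfig(dt=0.01, t_end=1.0)
        with pytest.raises(ValueError, match="label"):
            run_mpippet({"a": t, "b": t}, EventStream(np.array([0.5])), cfg)

    def test_unknown_label_rejected(self):
        t = ExpectationTemplate(lambda_0=0.5)
        cfg = FilterConfig(dt=0.01, t_end=1.0)
        with pytest.raises(ValueError, match="label"):
            run_mpippet(
                {"a": t}, EventStream(np.array([0.5]), labels=("b",)), cfg
            )

    def test_simultaneous_events_across_streams_allowed(self):
        t = ExpectationTemplate(lambda_0=0.5)
        stream = EventStream(np.array([0.5, 0.5]), labels=("a", "b"))
        cfg = FilterConfig(dt=0.01, t_end=1.0)
        traj = run_mpippet({"a": t, "b": t}, stream, cfg)
        assert list(traj.event_marks) == [50]


class TestPlanNextTap:
    def test_simple_extrapolation(self):
        taps = make_isochronous_template(0.5, (0.0, 5.0), strength=1.0, variance=0.001)
        t = plan_next_tap(GaussianBelief1D(mu=0.4, V=0.01), taps, now=1.0)
        assert t == pytest.approx(1.1)

    def test_tie_break_schedules_next_interval(self):
        taps = make_isochronous_template(0.5, (0.0, 5.0), strength=1.0, variance=0.001)
        t = plan_next_tap(GaussianBelief1D(mu=0.5, V=0.01), taps, now=1.0)
        assert t == pytest.approx(1.5)

    def test_no_future_peak_raises(self):
        taps = make_isochronous_template(0.5, 2, strength=1.0, variance=0.001)
        with pytest.raises(ValueError, match="horizon"):
            plan_next_tap(GaussianBelief1D(mu=2.0, V=0.01), taps, now=0.0)

    def test_planned_taps_stay_near_grid(self):
        # regression over a tracked run: planned taps within one tap
        # interval of the true 0.5 s grid
        tap_period = 0.5
        taps = make_isochronous_template(tap_period, (0.0, 10.0), strength=1.0,
                                         variance=0.001)
        t = make_isochronous_template(0.5, 8, strength=0.8, variance=0.001,
                                      lambda_0=0.02)
        cfg = FilterConfig(dt=0.001, sigma=0.1, t_end=3.6)
        traj = run_pippet(t, metronome(0.5, 7, start=0.5), cfg)
        for k in traj.event_marks:
            belief = GaussianBelief1D(mu=traj.mu[k], V=traj.V[k])
            tap = plan_next_tap(belief, taps, now=traj.times[k])
            nearest = round(tap / tap_period) * tap_period
            assert abs(tap - nearest) < tap_period
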