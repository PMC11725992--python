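"""Bayesian observer: channel responses, likelihood decode, adaptation
dynamics, prior integration, AUC decision, full sequential simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seradapt as sa
from seradapt.observer import (AdaptationParams, ChannelBank, ContrastParams,
                               ObserverParams, OrientationGrid,
                               apply_adaptation, channel_response,
                               circular_mean_deg, compute_posterior,
                               decision_probability, encode_likelihood,
                               load_presets, recover_gains, simulate_observer,
                               update_prior, vm_pmf)

GRID = OrientationGrid()


def fresh(kappa_phi=1.2, n=60):
    return ChannelBank(n_channels=n, kappa_phi=kappa_phi, grid=GRID)


CP = ContrastParams(c50=0.082, c_exp=2.35, w50=0.09, eps_exp=2.3,
                    contrast_variant="CV")
CP_CI = ContrastParams(c50=0.082, c_exp=2.35, contrast_variant="CI")


class TestChannelResponse:
    def test_peak_at_preferred_and_c1(self):
        bank = fresh()
        r = channel_response(bank.preferred[10], 1.0, bank, CP_CI)
        assert r[10] == pytest.approx(1.0)
        assert np.all(r <= r[10] + 1e-12)

    def test_semi_saturation_is_half_the_asymptote(self):
        """At c = c50 the response gain is exactly half the large-contrast
        asymptote of the saturation curve (checked against the c=1-normalised
        implementation, whose asymptote is c50^c_exp + 1)."""
        bank = fresh()
        peak_c50 = channel_response(0.0, CP_CI.c50, bank, CP_CI).max()
        asymptote = CP_CI.c50 ** CP_CI.c_exp + 1.0
        assert peak_c50 == pytest.approx(asymptote / 2.0)

    def test_vanishes_at_zero_contrast(self):
        bank = fresh()
        assert channel_response(0.0, 1e-9, bank, CP).max() < 1e-12
        with pytest.raises(ValueError):
            channel_response(0.0, 0.0, bank, CP)

    def test_cv_tuning_broadens_at_low_contrast(self):
        bank = fresh()
        hi = channel_response(0.0, 0.5, bank, CP)
        lo = channel_response(0.0, 0.08, bank, CP)
        # half-width of the (peak-normalised) profile is wider at low contrast
        width = lambda r: np.sum(r / r.max() > 0.5)
        assert width(lo) > width(hi)
        ci_hi = channel_response(0.0, 0.5, bank, CP_CI)
        ci_lo = channel_response(0.0, 0.08, bank, CP_CI)
        assert width(ci_lo) == width(ci_hi)


class TestLikelihood:
    def test_mode_at_stimulus_for_fresh_bank(self):
        bank = fresh()
        L = encode_likelihood(channel_response(12.0, 1.0, bank, CP), bank, 15.0)
        assert GRID.values[np.argmax(L)] == pytest.approx(12.0, abs=GRID.resolution)
        assert L.sum() == pytest.approx(1.0)

    def test_omega_zero_gives_uniform(self):
        bank = fresh()
        L = encode_likelihood(channel_response(0.0, 0.5, bank, CP), bank, 0.0)
        assert np.allclose(L, 1.0 / GRID.size)

    def test_zero_drive_gives_uniform(self):
        bank = fresh()
        L = encode_likelihood(np.zeros(bank.n_channels), bank, 15.0)
        assert np.allclose(L, 1.0 / GRID.size)

    def test_matches_von_mises_vector_sum_oracle(self):
        """The decoded likelihood is exactly von Mises: its circular mean must
        equal the argument of sum_i w_i e^{i z_i} (closed form), for an
        arbitrarily adapted bank."""
        rng = np.random.default_rng(5)
        bank = fresh()
        bank.gains = rng.uniform(0.3, 1.0, bank.n_channels)
        resp = channel_response(-4.0, 0.5, bank, CP)
        L = encode_likelihood(resp, bank, 15.0)
        w = bank.gains * resp
        z = np.deg2rad(2.0 * bank.preferred)
        mode = np.rad2deg(np.angle(np.sum(w * np.exp(1j * z)))) / 2.0
        assert circular_mean_deg(GRID, L) == pytest.approx(mode, abs=1e-6)

    def test_repulsion_sign_and_contrast_ordering(self):
        """A clockwise adaptor pushes the likelihood mode counterclockwise
        (repulsion), and the mode displacement grows as the test's tuning
        broadens — so in the CV variant the low-contrast test shifts at least
        as much as the high-contrast one."""
        shifts = {}
        for c_test in (0.5, 0.08):
            bank = fresh()
            apply_adaptation(bank, channel_response(-5.66, 0.5, bank, CP), 0.2)
            L = encode_likelihood(channel_response(0.0, c_test, bank, CP),
                                  bank, 15.0)
            shifts[c_test] = circular_mean_deg(GRID, L)
        assert shifts[0.5] > 0 and shifts[0.08] > 0      # away from the adaptor
        assert shifts[0.08] >= shifts[0.5]               # wider test, larger shift


class TestAdaptationDynamics:
    def test_zero_response_leaves_gain(self):
        bank = fresh()
        g0 = bank.gains.copy()
        apply_adaptation(bank, np.zeros(bank.n_channels), 0.3)
        assert np.array_equal(bank.gains, g0)

    def test_direct_update(self):
        bank = fresh(n=3)
        apply_adaptation(bank, np.array([1.0, 0.5, 0.0]), 0.2)
        assert np.allclose(bank.gains, [0.8, 0.9, 1.0])

    def test_repeated_adaptation_geometric_and_bounded(self):
        bank = fresh(n=1)
        n = np.array([0.7])
        for t in range(1, 6):
            apply_adaptation(bank, n, 0.3)
            assert bank.gains[0] == pytest.approx((1 - 0.3 * 0.7) ** t)
        assert 0 < bank.gains[0] <= 1

    def test_recovery_arithmetic_and_cap(self):
        bank = fresh(n=1)
        bank.gains = np.array([0.5])
        recover_gains(bank, beta=0.5, dt=1.0)
        assert bank.gains[0] == pytest.approx(0.75)
        recover_gains(bank, beta=2.0, dt=1.0)      # beta*dt >= 1: full recovery
        assert bank.gains[0] == 1.0
        bank.gains = np.array([0.5])
        recover_gains(bank, beta=0.5, dt=0.0)
        assert bank.gains[0] == 0.5
        with pytest.raises(ValueError):
            recover_gains(bank, 0.5, -0.1)

    @given(st.lists(st.tuples(st.floats(-80, 80), st.floats(0.05, 1.0),
                              st.floats(0, 3)), min_size=1, max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_gains_stay_in_unit_interval(self, steps):
        bank = fresh()
        for theta, c, dt in steps:
            recover_gains(bank, 0.2, dt)
            apply_adaptation(bank, channel_response(theta, c, bank, CP), 0.3)
            assert np.all(bank.gains > 0) and np.all(bank.gains <= 1)


class TestPriorAndPosterior:
    def test_prior_update_endpoints_and_normalisation(self):
        prior = vm_pmf(GRID, 0.0, 5.0)
        post = vm_pmf(GRID, 10.0, 5.0)
        assert np.allclose(update_prior(prior, post, 0.0), prior)
        assert np.allclose(update_prior(prior, post, 1.0), post)
        mixed = update_prior(prior, post, 0.3)
        assert mixed.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            update_prior(prior, post, 1.5)

    def test_uniform_prior_returns_likelihood(self):
        L = vm_pmf(GRID, 7.0, 30.0)
        u = np.full(GRID.size, 1.0 / GRID.size)
        assert np.allclose(compute_posterior(L, u), L)

    def test_product_of_equal_von_mises_doubles_concentration(self):
        a = vm_pmf(GRID, 5.0, 12.0)
        assert np.allclose(compute_posterior(a, a), vm_pmf(GRID, 5.0, 24.0),
                           atol=1e-12)

    def test_prior_pull_stronger_on_low_contrast_tests(self):
        """A peaked prior drags the wide low-contrast likelihood further than
        the narrow high-contrast one."""
        prior = vm_pmf(GRID, 15.0, 8.0)
        pulls = {}
        for c in (0.5, 0.08):
            bank = fresh()
            L = encode_likelihood(channel_response(0.0, c, bank, CP), bank, 15.0)
            pulls[c] = circular_mean_deg(GRID, compute_posterior(L, prior))
        assert pulls[0.08] > pulls[0.5] > 0

    def test_zero_mass_product_rejected(self):
        a = np.zeros(GRID.size); a[0] = 1.0
        b = np.zeros(GRID.size); b[-1] = 1.0
        with pytest.raises(ValueError):
            compute_posterior(a, b)


class TestDecision:
    def test_identical_distributions_give_half(self):
        ref = vm_pmf(GRID, 0.0, 200.0)
        assert decision_probability(ref, ref, GRID, 0.0) == pytest.approx(0.5)

    def test_fully_ccw_posterior_gives_one(self):
        ref = np.zeros(GRID.size); ref[GRID.size // 2] = 1.0     # mass at 0 deg
        post = np.zeros(GRID.size); post[GRID.size // 2 + 40] = 1.0
        assert decision_probability(post, ref, GRID, 0.0) == 1.0

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(11)
        post = vm_pmf(GRID, 1.3, 60.0)
        ref = vm_pmf(GRID, -0.4, 150.0)
        n = 10**6
        x = rng.choice(GRID.values, size=n, p=post)
        y = rng.choice(GRID.values, size=n, p=ref)
        mc = np.mean(x > y) + 0.5 * np.mean(x == y)
        got = decision_probability(post, ref, GRID, -0.4)
        assert got == pytest.approx(mc, abs=1e-3)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            decision_probability(np.ones(10) / 10, np.ones(20) / 20, GRID)


class TestSimulateObserver:
    def test_static_observer_is_time_invariant(self, design):
        """alpha=0, tau=0, beta arbitrary: every test's probability depends
        only on its own type."""
        prof = sa.sample_participant("B", design, seed=301)
        events = sa.generate_session(prof, design, seed=302)
        params = ObserverParams.from_preset(
            "V5", "CV", AdaptationParams(alpha=0.0, beta=0.1, tau=0.0))
        probs = simulate_observer(events, prof, params)
        tests = [e for e in events if e.is_test]
        for tt in ("HC+", "LC+", "HC-", "LC-"):
            vals = [p for e, p in zip(tests, probs) if e.test_type == tt]
            assert np.ptp(vals) < 1e-12

    def test_group_b_block_ii_hc_plus_toward_chance(self, design):
        prof = sa.sample_participant("B", design, seed=303)
        events = sa.generate_session(prof, design, seed=304)
        probs = simulate_observer(events, prof,
                                  ObserverParams.from_preset("V5", "CV"))
        tests = [e for e in events if e.is_test]
        b1, b2 = design.block_boundaries
        p_i = np.mean([p for e, p in zip(tests, probs)
                       if e.index < b1 and e.test_type == "HC+"])
        p_ii = np.mean([p for e, p in zip(tests, probs)
                        if b1 <= e.index < b2 and e.test_type == "HC+"])
        assert abs(p_ii - 0.5) < abs(p_i - 0.5)

    def test_duration_contrast_non_equivalence(self, design):
        """High-contrast stimuli shortened to match the low-contrast
        likelihood drive still adapt like high-contrast stimuli, so the
        sequential predictions differ from genuinely low-contrast streams."""
        params = ObserverParams.from_preset("V5", "CI")
        prof = sa.sample_participant("C", design, seed=305)
        events = sa.generate_session(prof, design, seed=306)
        d_eq = sa.equivalent_duration(prof.low_contrast, prof.high_contrast,
                                      params.contrast)
        swapped = [sa.StimulusEvent(e.index, e.orientation, prof.high_contrast,
                                    d_eq, e.onset, e.role, e.test_type)
                   if (not e.is_test and e.contrast == prof.low_contrast) else e
                   for e in events]
        p_orig = simulate_observer(events, prof, params)
        p_swap = simulate_observer(swapped, prof, params)
        # matched drive: identical static likelihoods...
        bank = params.make_bank()
        L_low = encode_likelihood(
            channel_response(0.0, prof.low_contrast, bank, params.contrast),
            bank, params.adaptation.omega)
        L_eq = encode_likelihood(
            channel_response(0.0, prof.high_contrast, bank, params.contrast),
            bank, params.adaptation.omega * d_eq / 0.3)
        assert np.allclose(L_low, L_eq, atol=1e-10)
        # ...but different serial predictions
        assert np.max(np.abs(p_orig - p_swap)) > 0.01

    def test_all_distributions_normalised_in_traces(self, design):
        prof = sa.sample_participant("A", design, seed=307)
        events = sa.generate_session(prof, design, seed=308)[:120]
        probs, tr = simulate_observer(events, prof,
                                      ObserverParams.from_preset("V5", "CV"),
                                      trace=True)
        assert np.all((probs >= 0) & (probs <= 1))
        assert all(np.all(g > 0) and np.all(g <= 1) for g in tr.gains)

    def test_presets_load_and_differ(self):
        presets = load_presets()
        assert set(presets) >= {"V1", "V2", "V5"}
        p = ObserverParams.from_preset("V1", "CI")
        assert p.n_free_params == 4
        assert ObserverParams.from_preset("V5", "CV").n_free_params == 6
        with pytest.raises(KeyError):
            ObserverParams.from_preset("V9")
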