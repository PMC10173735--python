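"""Model-core behaviour: algebraic pieces, RHS limits, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctldyn.calibration import basal_growth_rate, steady_state_ratio
from ctldyn.model import (InputSignals, StateVector, arrest_factor,
                          ctl_activity, exhaustion_level, initial_state,
                          rhs_basic, rhs_full, simulate, simulate_fast)
from ctldyn.params import TumorImmuneParams


def basal(kgs=1.64, ksg=0.66, **kw):
    return TumorImmuneParams(kgs=kgs, ksg=ksg, **kw)


class TestAlgebra:
    def test_arrest_factor_closed_form(self):
        assert arrest_factor(5.0, 2.0, 0.0) == 1.0
        # 1/ki is the IFNG concentration halving the transition rate
        assert arrest_factor(1.0 / 4.40, 1.0, 4.40) == pytest.approx(0.5)
        assert arrest_factor(1.64, 1.0, 8.1) == pytest.approx(
            1 / (1 + 8.1 * 1.64))
        assert arrest_factor(1.64, 1.0, 8.1) == pytest.approx(0.07, abs=0.005)

    def test_arrest_factor_rejects_empty_tumor(self):
        with pytest.raises(ValueError):
            arrest_factor(1.0, 0.0, 1.0)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 50))
    @settings(max_examples=50, deadline=None)
    def test_arrest_factor_monotone_decreasing(self, i1, delta, ki):
        v = 3.0
        assert arrest_factor(i1 + delta, v, ki) < arrest_factor(i1, v, ki)

    def test_activity_limits(self):
        assert ctl_activity(0.0, 1.0) == 1.0
        assert ctl_activity(1.0, 1.0) == 0.5  # half-effect at R = 1/kex
        assert ctl_activity(1e12, 1.0) == pytest.approx(0.0, abs=1e-10)

    @given(st.floats(0.0, 1e3), st.floats(1e-6, 1e3), st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_activity_monotone_decreasing(self, r, delta, kex):
        assert ctl_activity(r + delta, kex) < ctl_activity(r, kex)

    def test_exhaustion_terms(self):
        p0 = basal(kl=0.0, kt=0.0, kp=0.0)
        s = StateVector(S=1, G=1, E=1, L=2, H=3, P=2, PL=3)
        assert exhaustion_level(s, p0) == 0.0
        p_l = basal(kl=1.0)
        assert exhaustion_level(StateVector(S=1, G=1, E=1, L=2), p_l) == 2.0
        p_p = basal(kp=1.0)
        assert exhaustion_level(
            StateVector(S=0.5, G=0.5, E=1, P=2, PL=3), p_p) == 6.0

    def test_exhaustion_no_ctls_means_no_exhaustion(self):
        p = basal(kl=1.0, kt=1.0, kp=1.0)
        assert exhaustion_level(StateVector(S=1, G=1, E=0, L=5, H=5), p) == 0.0


class TestRhs:
    def test_basic_direct_substitution(self):
        dy = rhs_basic(StateVector(S=1.0, G=1.0), basal())
        assert dy[0] == pytest.approx(1.64 - 0.66)   # dS/dt = 0.98
        assert dy[1] == pytest.approx(-1.64 + 2 * 0.66)  # dG/dt = -0.32
        assert np.all(dy[2:] == 0.0)

    def test_state_rejects_negative_components(self):
        with pytest.raises(ValueError):
            StateVector(S=-1.0, G=1.0)

    def test_arrest_limit_mass_ends_in_g1(self):
        # kgs = 0: nothing leaves G1, total volume converges to a constant
        p = basal(kgs=0.0, ksg=0.8)
        traj = simulate(p, StateVector(S=5.0, G=1.0), np.linspace(0, 40, 20))
        v = traj["V"].to_numpy()
        assert traj["S"].iloc[-1] == pytest.approx(0.0, abs=1e-8)
        assert v[-1] == pytest.approx(v[-2], rel=1e-6)

    def test_full_reduces_to_basic_without_ctls(self):
        p = basal(s0=0.0, se=5.0, dE=1.0, di=1.0, ki=3.0, ke=10.0,
                  kl=1.0, kt=1.0, kp=1.0)
        s = StateVector(S=2.0, G=3.0)
        assert rhs_full(s, p) == pytest.approx(rhs_basic(s, p))

    def test_killing_split_by_compartment_fractions(self):
        # alpha = 1 (no checkpoints), ke*E = 1 total, S = G -> 0.5 each
        p = TumorImmuneParams(kgs=0.0, ksg=0.0, ke=100.0)
        dy = rhs_full(StateVector(S=50.0, G=50.0, E=0.01), p)
        assert dy[0] == pytest.approx(-0.5)
        assert dy[1] == pytest.approx(-0.5)

    def test_infiltration_gated_by_transfer_day(self):
        p = basal(s0=0.01)
        s = StateVector(S=50.0, G=50.0)
        assert rhs_full(s, p)[2] == pytest.approx(0.01 * 100.0)
        assert rhs_full(s, p, infiltration=False)[2] == 0.0


class TestSimulate:
    def test_exponential_limit_matches_eigenvalue(self):
        # no CTLs: V(t) = V(0) exp(lambda_max t) to 1e-6 relative
        p = basal(s0=0.0, ke=0.0, ki=0.0)
        lam = basal_growth_rate(p.kgs, p.ksg)
        init = initial_state(p, v0=50.0)
        times = np.linspace(0, 10, 21)
        traj = simulate(p, init, times)
        expected = 50.0 * np.exp(lam * times)
        np.testing.assert_allclose(traj["V"], expected, rtol=1e-6)

    def test_fast_path_agrees_with_lsoda(self, mild_params):
        init = initial_state(mild_params, v0=100.0, t0=-1.0)
        times = np.linspace(-1, 14, 31)
        ref = simulate(mild_params, init, times)
        ys = simulate_fast(mild_params, init, times)
        np.testing.assert_allclose(
            ys, ref[["S", "G", "E", "I", "P", "PL", "L", "H"]], rtol=1e-5,
            atol=1e-8)

    def test_nonnegative_trajectories(self, rng):
        for _ in range(5):
            p = basal(s0=10 ** rng.uniform(-3, 0), se=rng.uniform(0.5, 6),
                      dE=rng.uniform(0.1, 2), di=rng.uniform(0.5, 5),
                      ki=rng.uniform(0, 10), ke=rng.uniform(0, 20),
                      kl=rng.uniform(0, 2), kt=rng.uniform(0, 2),
                      kp=rng.uniform(0, 0.5), dl=rng.uniform(0.05, 5),
                      dt=rng.uniform(0.05, 5), dp=rng.uniform(0.05, 5),
                      dpl=rng.uniform(0.05, 5))
            traj = simulate(p, initial_state(p, v0=100.0, t0=-1.0),
                            np.linspace(-1, 14, 61))
            assert (traj[["S", "G", "E", "I", "P", "PL", "L", "H"]].to_numpy()
                    >= 0).all()

    def test_reference_course_ctl_wave_follows_ifng_peak(self, ref_params):
        # CTLs rise then fall; intratumoral IFNG peaks no later than CTLs
        times = np.linspace(-1, 14, 301)
        traj = simulate(ref_params, initial_state(ref_params, v0=100.0, t0=-1.0),
                        times)
        e = traj["E"].to_numpy()
        i = traj["I"].to_numpy()
        assert 0 < np.argmax(e) < len(e) - 1          # rises then falls
        assert e[-1] < 0.05 * e.max()
        assert np.argmax(i) <= np.argmax(e)

    def test_checkpoint_decay_rates_do_not_feed_back_without_weights(self):
        # with all exhaustion weights zero the S,G,E,I subsystem is
        # independent of the checkpoint block
        times = np.linspace(-1, 10, 23)
        base = dict(s0=0.01, se=2.0, dE=0.5, di=2.0, ki=3.0, ke=2.0,
                    kl=0.0, kt=0.0, kp=0.0)
        pa = basal(**base, dl=0.05, dt=0.05, dp=0.05, dpl=0.05)
        pb = basal(**base, dl=50.0, dt=50.0, dp=50.0, dpl=50.0)
        ta = simulate(pa, initial_state(pa, t0=-1.0), times)
        tb = simulate(pb, initial_state(pb, t0=-1.0), times)
        np.testing.assert_allclose(ta[["S", "G", "E", "I"]],
                                   tb[["S", "G", "E", "I"]], rtol=1e-5)
        assert not np.allclose(ta["L"], tb["L"])


class TestForcedMode:
    def test_zero_inputs_match_unforced_basal(self):
        p = basal(ke=5.0, ki=5.0)
        inputs = InputSignals.from_means([0, 14], [0, 0], [0, 14], [0, 0])
        times = np.linspace(0, 10, 21)
        init = initial_state(p)
        forced = simulate(p, init, times, inputs=inputs)
        unforced = simulate(p.with_values(s0=0.0), init, times)
        np.testing.assert_allclose(forced[["S", "G"]], unforced[["S", "G"]],
                                   rtol=1e-7)

    def test_own_trajectory_inputs_reproduce_unforced_tumor(self, mild_params):
        # feeding the unforced model's own E(t), I(t) back as inputs
        # must reproduce its S, G courses (up to interpolation density);
        # forced mode carries no exhaustion, so compare at zero weights
        p = mild_params.with_values(kl=0.0, kt=0.0, kp=0.0)
        dense = np.linspace(0.0, 10.0, 401)
        ref = simulate(p, initial_state(p), dense)
        inputs = InputSignals.from_means(dense, ref["E"], dense, ref["I"])
        sparse = dense[::20]
        forced = simulate(p, initial_state(p), sparse, inputs=inputs)
        np.testing.assert_allclose(forced["V"],
                                   ref["V"].to_numpy()[::20], rtol=2e-3)

    def test_ifng_spike_dips_cycle_ratio_then_recovers(self):
        p = basal(ke=0.0, ki=8.1)
        inputs = InputSignals.from_means(
            [0, 14], [0, 0], [0, 2.9, 3, 3.1, 6, 14], [0, 0, 600, 600, 0, 0])
        times = np.linspace(0, 14, 141)
        traj = simulate(p, initial_state(p), times, inputs=inputs)
        r = traj["ratio_SG"].to_numpy()
        r_ss = steady_state_ratio(p.kgs, p.ksg)
        assert r[:30].min() > 0.9 * r_ss       # before the spike
        assert r.min() < 0.5 * r_ss            # arrest dips the ratio
        assert r[-1] > 0.9 * r_ss              # recovery after IFNG clears

    def test_input_signals_interpolation_contract(self):
        sig = InputSignals.from_means([1, 3, 5], [10, 30, 20], [1, 3], [2, 4])
        assert sig.E_of_t(3) == 30.0                   # knot exact
        assert sig.E_of_t(2) == pytest.approx(20.0)    # linear between
        assert sig.E_of_t(-5) == 10.0                  # clamped left
        assert sig.E_of_t(99) == 20.0                  # clamped right
        with pytest.raises(ValueError):
            InputSignals.from_means([3, 1], [1, 2], [0, 1], [0, 1])
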