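"""Gating kinetics, Markov schemes, and the calcium pool."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grcopt.channels import (CalciumPool, GateSpec, HHChannelSpec,
                             MarkovChannelSpec, RateFn, calcium_reversal,
                             channel_current, gate_steady_state,
                             markov_step, resurgent_na_13state,
                             update_calcium)
from grcopt.kinetics import load_kinetics

VGRID = np.arange(-100.0, 60.0, 1.0)


class TestGates:
    def test_equal_rates_give_half_activation(self):
        g = GateSpec("m", 1, alpha=RateFn("constant", 2.0),
                     beta=RateFn("constant", 2.0))
        minf, tau = gate_steady_state(g, -40.0)
        assert minf == pytest.approx(0.5)

    def test_closed_form_alpha_beta(self):
        g = GateSpec("m", 1, alpha=RateFn("constant", 1.0),
                     beta=RateFn("constant", 3.0))
        minf, tau = gate_steady_state(g, 0.0)
        assert minf == pytest.approx(0.25)
        assert tau == pytest.approx(0.25)

    def test_nonfinite_voltage_rejected(self):
        g = GateSpec("m", 1, alpha=RateFn("constant", 1.0),
                     beta=RateFn("constant", 3.0))
        with pytest.raises(ValueError):
            gate_steady_state(g, math.nan)

    def test_kir_activation_decreases_with_depolarization(self):
        kin = load_kinetics("grc2026a")
        d = kin.gates("Kir")[0]
        minf = np.array([gate_steady_state(d, v)[0]
                         for v in np.arange(-100.0, -40.0, 1.0)])
        assert np.all(np.diff(minf) < 0)

    @pytest.mark.parametrize("channel", ["Na", "Nap", "Nar", "KV", "KA",
                                         "Kslow", "Kir", "Ca-HVA"])
    def test_shipped_gates_bounded_and_positive_tau(self, channel):
        kin = load_kinetics("grc2026a")
        for g in kin.gates(channel):
            minf, tau = gate_steady_state(g, VGRID)
            assert np.all((minf >= 0) & (minf <= 1))
            assert np.all(tau > 0)

    def test_kca_gate_needs_calcium(self):
        kin = load_kinetics("grc2026a")
        c = kin.gates("KCa")[0]
        with pytest.raises(ValueError):
            gate_steady_state(c, -50.0)
        minf, tau = gate_steady_state(c, -50.0, ca=1e-4)
        assert 0 <= minf <= 1 and tau > 0


class TestChannelCurrent:
    leak = HHChannelSpec("Lkg1", (), gmax=5.68e-2, erev=-58.0)
    na_like = HHChannelSpec(
        "toy", (GateSpec("m", 2, alpha=RateFn("constant", 1.0),
                         beta=RateFn("constant", 1.0)),
                GateSpec("h", 1, alpha=RateFn("constant", 1.0),
                         beta=RateFn("constant", 1.0))),
        gmax=10.0, erev=50.0)

    def test_closed_gate_blocks_current(self):
        assert channel_current(self.na_like, [0.7, 0.0], -20.0) == 0.0

    def test_leak_density_hand_value(self):
        # G (V - E): 5.68e-2 mS/cm^2 * 10 mV = 5.68e-4 mA/cm^2, outward
        assert channel_current(self.leak, [], -48.0) == \
            pytest.approx(5.68e-4)

    def test_reversal_potential_zeroes_current(self):
        assert channel_current(self.na_like, [0.5, 0.5], 50.0) == 0.0

    def test_gate_state_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            channel_current(self.na_like, [1.2, 0.5], 0.0)

    def test_outward_positive_sign_convention(self):
        assert channel_current(self.na_like, [1.0, 1.0], 0.0) < 0  # inward
        assert channel_current(self.leak, [], -40.0) > 0           # outward


def two_state(k12, k21):
    return MarkovChannelSpec(
        "toy2", ("C", "O"),
        ((0, 1, RateFn("constant", k12)), (1, 0, RateFn("constant", k21))),
        open_states=(1,), gmax=1.0, erev=0.0)


class TestMarkov:
    def test_zero_rates_leave_occupancy_unchanged(self):
        spec = two_state(0.0, 0.0)
        p = markov_step(spec, [0.3, 0.7], -60.0, 0.5)
        assert np.allclose(p, [0.3, 0.7])

    def test_symmetric_two_state_converges_to_half(self):
        spec = two_state(1.0, 1.0)
        p = np.array([1.0, 0.0])
        for _ in range(2000):
            p = markov_step(spec, p, -60.0, 0.05)
        assert np.allclose(p, [0.5, 0.5], atol=1e-6)

    def test_three_state_stationary_matches_nullspace(self):
        spec = MarkovChannelSpec(
            "toy3", ("A", "B", "C"),
            ((0, 1, RateFn("constant", 0.7)), (1, 0, RateFn("constant", 0.2)),
             (1, 2, RateFn("constant", 0.4)), (2, 1, RateFn("constant", 0.9)),
             (2, 0, RateFn("constant", 0.1)), (0, 2, RateFn("constant", 0.3))),
            open_states=(2,), gmax=1.0, erev=0.0)
        p = np.array([1.0, 0.0, 0.0])
        for _ in range(4000):
            p = markov_step(spec, p, -60.0, 0.05)
        # oracle: null space of Q^T by direct linear algebra
        q = spec.rate_matrix(-60.0)
        w, vecs = np.linalg.eig(q.T)
        k = int(np.argmin(np.abs(w)))
        stat = np.real(vecs[:, k])
        stat = stat / stat.sum()
        assert np.allclose(p, stat, atol=1e-7)

    def test_resurgent_scheme_generator_rows_sum_to_zero(self):
        spec = MarkovChannelSpec("Na13", gmax=1.0, erev=87.39,
                                 **resurgent_na_13state())
        for v in (-80.0, -40.0, 0.0, 30.0):
            q = spec.rate_matrix(v)
            assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_occupancy_conserved_over_one_second(self):
        spec = MarkovChannelSpec("Na13", gmax=1.0, erev=87.39,
                                 **resurgent_na_13state())
        p = spec.equilibrium(-70.0)
        rng = np.random.default_rng(0)
        t = 0.0
        while t < 1000.0:
            v = -70.0 + 50.0 * np.sin(t / 30.0) + rng.normal(0, 2)
            p = markov_step(spec, p, v, 0.025)
            assert abs(p.sum() - 1.0) < 1e-9
            t += 0.025

    def test_equilibrium_mostly_closed_at_rest(self):
        spec = MarkovChannelSpec("Na13", gmax=1.0, erev=87.39,
                                 **resurgent_na_13state())
        p = spec.equilibrium(-70.0)
        assert spec.open_fraction(p) < 0.01


class TestCalciumPool:
    pool = CalciumPool(ca_mM=1e-4, ca_rest_mM=1e-4, ca_out_mM=2.0,
                       beta_ca=1.5, shell_depth_um=0.2)

    def test_rest_is_fixed_point(self):
        out = update_calcium(self.pool, 0.0, 1.0)
        assert out.ca_mM == pytest.approx(self.pool.ca_rest_mM)

    def test_free_decay_closed_form(self):
        import dataclasses
        p = dataclasses.replace(self.pool, ca_mM=2e-4)
        dt = 1.0 / self.pool.beta_ca  # integrate to t = 1/beta
        out = update_calcium(p, 0.0, dt)
        expected = 1e-4 * (1 + math.exp(-1))
        assert out.ca_mM == pytest.approx(expected, rel=0.01)

    def test_constant_influx_steady_state(self):
        i_ca = -0.01  # inward, mA/cm^2
        p = self.pool
        for _ in range(200):
            p = update_calcium(p, i_ca, 0.5)
        k = self.pool.influx_coeff()
        expected = 1e-4 + k * 0.01 / 1.5
        assert p.ca_mM == pytest.approx(expected, rel=0.005)

    def test_floor_clamp_warns(self):
        with pytest.warns(RuntimeWarning):
            out = update_calcium(self.pool, 1.0, 5.0)  # strong outward
        assert out.ca_mM >= 1e-6


class TestCalciumReversal:
    def test_equal_concentrations_zero(self):
        p = CalciumPool(ca_mM=2.0, ca_out_mM=2.0)
        assert calcium_reversal(p) == pytest.approx(0.0)

    def test_standard_concentrations_match_printed_value(self):
        # 2 mM outside / 100 nM inside at 30 degC -> the Ca-HVA reversal
        p = CalciumPool(ca_mM=1e-4, ca_out_mM=2.0, temp_c=30.0)
        assert calcium_reversal(p) == pytest.approx(129.33, abs=0.1)

    def test_ratio_dependence(self):
        p1 = CalciumPool(ca_mM=1e-4, ca_out_mM=2.0)
        p2 = CalciumPool(ca_mM=2e-4, ca_out_mM=4.0)
        assert calcium_reversal(p1) == pytest.approx(calcium_reversal(p2))

    def test_monotone_decreasing_in_internal_ca(self):
        es = [calcium_reversal(CalciumPool(ca_mM=c, ca_out_mM=2.0))
              for c in (1e-5, 1e-4, 1e-3, 1e-2)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            calcium_reversal(CalciumPool(ca_mM=0.0))


@settings(max_examples=25, deadline=None)
@given(v=st.floats(-100, 60), dt=st.floats(0.005, 0.5))
def test_markov_step_preserves_distribution(v, dt):
    spec = MarkovChannelSpec("Na13", gmax=1.0, erev=87.39,
                             **resurgent_na_13state())
    p = spec.equilibrium(-65.0)
    out = markov_step(spec, p, v, dt)
    assert abs(out.sum() - 1.0) < 1e-9
    assert np.all(out >= 0)
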