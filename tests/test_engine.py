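"""Integrator correctness: closed forms, conservation, convergence."""

import numpy as np
import pytest

from grcopt.engine import (compile_model, simulate, simulate_batch, vclamp)
from grcopt.channels import MarkovChannelSpec, markov_step, \
    resurgent_na_13state
from grcopt.morphology import build_model
from grcopt.protocols import (StimulusProtocol, VClampProtocol,
                              step_protocol, zap_current, zap_cycle_edges,
                              zap_protocol)

from conftest import passive_mono, passive_multi


class TestPassiveClosedForms:
    def test_rc_charging_curve(self):
        """Passive sphere under a step follows V = V0 + IR(1-e^(-t/tau))
        to better than 0.5%."""
        m = passive_mono()
        pr = step_protocol(10.0, duration_ms=100.0, pre_ms=20.0)
        tr = simulate(m, pr, settle_ms=100.0)
        area = m.areas_cm2()[0]
        r_gohm = 1.0 / (0.0568 * area * 1e6)   # 1/nS
        tau = 1.0 / 0.0568                     # Cm/g, ms
        t, v = tr.t_ms, tr.voltage()
        on = (t >= 20.0) & (t <= 120.0)
        pred = -65.0 + 10.0 * r_gohm * (1 - np.exp(-(t[on] - 20.0) / tau))
        assert np.abs(v[on] - pred).max() < 0.005 * 10.0 * r_gohm

    def test_rest_is_stable_without_input(self, mono_model):
        pr = step_protocol(0.0, duration_ms=1000.0, pre_ms=0.0, post_ms=0.0)
        tr = simulate(mono_model, pr, settle_ms=500.0)
        v = tr.voltage()
        assert np.abs(v - v[0]).max() < 0.5

    def test_passive_vclamp_recovers_input_resistance(self):
        m = passive_mono()
        t, i_pa, v_rest = vclamp(m, VClampProtocol(), settle_ms=100.0)
        base = i_pa[(t > 30) & (t < 50)].mean()
        ss = i_pa[(t > 140) & (t < 150)].mean()
        r = -10.0 / (ss - base)
        area = m.areas_cm2()[0]
        assert r == pytest.approx(1.0 / (0.0568 * area * 1e6), rel=1e-3)

    def test_charge_conservation_passive_multi(self):
        """Injected charge = capacitive + leak charge within 1% over a
        subthreshold step."""
        m = passive_multi()
        cm = compile_model(m)
        pr = step_protocol(5.0, duration_ms=400.0, pre_ms=50.0, post_ms=0.0)
        tr = simulate(m, pr, record="all", settle_ms=300.0)
        t = tr.t_ms
        dt = tr.dt_ms
        on = (t >= 50.0)
        q_inj = 5.0 * (t[-1] - 50.0) * 1e-6  # pA*ms -> uA*ms
        v = np.vstack([tr.v_mV[c.label] for c in m.compartments])
        v0 = v[:, t < 50.0].mean(axis=1)
        q_cap = float(np.sum(cm.cm * (v[:, -1] - v0)))  # uF*mV = uA*ms
        g_leak = np.array([0.02 * a for a in cm.areas])  # mS per comp
        i_leak = (g_leak[:, None] * (v[:, on] - v0[:, None]))
        q_leak = float(np.sum(i_leak) * dt)
        assert q_cap + q_leak == pytest.approx(q_inj, rel=0.01)

    def test_voltage_attenuation_soma_to_dendrite_below_2pct(self):
        m = passive_multi()
        pr = step_protocol(5.0, duration_ms=600.0, pre_ms=50.0, post_ms=0.0)
        tr = simulate(m, pr, record=("soma", "dendrite_1"), settle_ms=300.0)
        t = tr.t_ms
        ss = t > 500.0
        ds = tr.v_mV["soma"][ss].mean() - tr.v_mV["soma"][t < 50].mean()
        dd = tr.v_mV["dendrite_1"][ss].mean() - \
            tr.v_mV["dendrite_1"][t < 50].mean()
        assert abs(ds - dd) / abs(ds) < 0.02


class TestStimuli:
    def test_zap_zero_at_t0_and_bounded(self):
        t = np.linspace(0.0, 30000.0, 100001)
        i = zap_current(10.0, np.pi * 10.0 / 30.0, t)
        assert i[0] == 0.0
        assert np.max(np.abs(i)) <= 10.0 + 1e-12

    def test_zap_zero_crossings_match_closed_form(self):
        b = np.pi * 10.0 / 30.0  # 0-10 Hz over 30 s
        t = np.arange(0.05, 30000.0, 0.05)
        i = zap_current(10.0, b, t)
        sgn = np.sign(i)
        idx = np.flatnonzero((sgn[:-1] != sgn[1:]) & (sgn[:-1] != 0))
        # linear interpolation of each crossing
        crossings = t[idx] - i[idx] * (t[idx + 1] - t[idx]) / \
            (i[idx + 1] - i[idx])
        # each detected crossing must sit at t_k = sqrt(k pi / B) for the
        # integer k it rounds to, and the k's must be consecutive
        k = np.rint(b * (crossings * 1e-3) ** 2 / np.pi).astype(int)
        expected = np.sqrt(k * np.pi / b) * 1e3
        assert np.array_equal(k, np.arange(1, len(k) + 1))
        assert np.allclose(crossings, expected, atol=0.05)

    def test_zap_protocol_sweeps_to_target_frequency(self):
        p = zap_protocol(10.0, f_max_hz=10.0, duration_ms=30000.0)
        # instantaneous frequency at the end: B*t/pi
        assert p.b_rad_s2 * 30.0 / np.pi == pytest.approx(10.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol("step", 100.0, 50.0, 10.0, 200.0)

    def test_zap_cycle_edges_increase(self):
        e = zap_cycle_edges(np.pi / 3.0, 30000.0)
        assert np.all(np.diff(e) > 0)


class TestMarkovInEngine:
    def test_expm_table_matches_forward_substepping(self):
        """The engine's matrix-exponential propagator and the explicit
        sub-stepped forward scheme agree at fixed voltage."""
        spec = MarkovChannelSpec("Na13", gmax=1.0, erev=87.39,
                                 **resurgent_na_13state())
        from scipy.linalg import expm
        for v in (-70.0, -40.0, 0.0):
            p0 = spec.equilibrium(-70.0)
            p_table = p0 @ expm(spec.rate_matrix(v) * 0.025)
            p_fwd = markov_step(spec, p0, v, 0.025, max_rate_dt=0.002)
            # forward scheme is first order in the substep; 2e-5 here
            assert np.allclose(p_table, p_fwd, atol=1e-4)


class TestConvergence:
    def test_halving_dt_converges_spike_timing(self, mono_model):
        """Halving the step leaves the discharge essentially unchanged:
        the first spikes shift by a fraction of a millisecond and the
        firing rate by well under 1% (the residual is a slow phase
        drift, so late spike times are compared through the ISIs)."""
        from grcopt.features import detect_spikes
        pr = step_protocol(16.0, duration_ms=500.0, pre_ms=50.0,
                           post_ms=0.0)
        sp = {}
        for dt in (0.025, 0.0125):
            tr = simulate(mono_model, pr, dt=dt, settle_ms=400.0)
            sp[dt] = detect_spikes(tr).times
        n = min(len(sp[0.025]), len(sp[0.0125]))
        assert n > 3
        assert abs(len(sp[0.025]) - len(sp[0.0125])) <= 1
        assert abs(sp[0.025][0] - sp[0.0125][0]) < 0.05
        isi_a = np.diff(sp[0.025][:n])
        isi_b = np.diff(sp[0.0125][:n])
        assert abs(isi_a.mean() - isi_b.mean()) / isi_b.mean() < 0.01

    def test_adaptive_matches_fixed_on_passive_step(self):
        m = passive_mono()
        pr = step_protocol(8.0, duration_ms=80.0, pre_ms=20.0)
        fixed = simulate(m, pr, settle_ms=50.0)
        adap = simulate(m, pr, solver="adaptive", settle_ms=50.0)
        vi = np.interp(fixed.t_ms, adap.t_ms, adap.voltage())
        assert np.abs(vi - fixed.voltage()).max() < 0.05


class TestBatch:
    def test_batch_rows_match_individual_runs(self, mono_model):
        g = mono_model.reference_vector()
        pr = step_protocol(1.0, duration_ms=300.0, pre_ms=50.0, post_ms=0.0)
        t, vb = simulate_batch(mono_model, np.tile(g, (2, 1)), pr,
                               settle_ms=200.0,
                               stim_scale=np.array([10.0, 22.0]))
        for amp, row in zip((10.0, 22.0), vb):
            pr1 = step_protocol(amp, duration_ms=300.0, pre_ms=50.0,
                                post_ms=0.0)
            tr = simulate(mono_model, pr1, settle_ms=200.0)
            assert np.allclose(tr.voltage(), row, atol=1e-9)

    def test_spatial_spike_order_ais_first(self, multi_model):
        """The action potential peaks first in the AIS, then soma and
        dendrites, then the distal axon."""
        from grcopt.features import detect_spikes
        pr = step_protocol(16.0, duration_ms=300.0, pre_ms=50.0,
                           post_ms=0.0)
        tr = simulate(multi_model, pr, record="all", settle_ms=400.0)
        times = {}
        for lab in ("AIS", "soma", "dendrite_1", "axon_15"):
            spt = detect_spikes(tr, label=lab, threshold=-30.0)
            assert spt.n > 0, lab
            times[lab] = spt.times[0]
        assert times["AIS"] < times["soma"] <= times["dendrite_1"]
        assert times["AIS"] < times["axon_15"]
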