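"""Spike detection, feature extraction, and objective scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grcopt.features import (FEATURE_NAMES, FeatureSet, FeatureTemplate,
                             MISSING_PENALTY, detect_spikes,
                             extract_features, objective_scores)
from grcopt.trace import VoltageTrace

from reference_features import ref_features


def gaussian_spike_trace(spike_times, dt=0.025, total=500.0, rest=-65.0,
                         amp=95.0, sigma=0.25):
    """Synthetic train of Gaussian-shaped spikes at known times."""
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, rest)
    for ts in spike_times:
        v += amp * np.exp(-0.5 * ((t - ts) / sigma) ** 2)
    return t, v


class TestDetection:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 100, 0.025)
        sp = detect_spikes((t, np.full_like(t, -65.0)))
        assert sp.n == 0

    def test_known_spike_times_recovered(self):
        times = [50.0, 120.0, 180.0, 260.0, 390.0]
        t, v = gaussian_spike_trace(times)
        sp = detect_spikes((t, v))
        assert sp.n == 5
        assert np.allclose(sp.times, times, atol=0.025)

    def test_threshold_above_peak_detects_nothing(self):
        t, v = gaussian_spike_trace([100.0])
        sp = detect_spikes((t, v), threshold=v.max() + 1)
        assert sp.n == 0

    def test_refractory_merges_double_crossings(self):
        t = np.arange(0, 50, 0.025)
        v = np.full_like(t, -65.0)
        v[(t > 10) & (t < 10.4)] = 10.0
        v[(t > 10.5) & (t < 10.9)] = 12.0  # re-crossing within 1 ms
        sp = detect_spikes((t, v))
        assert sp.n == 1

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.15, 0.4])
        with pytest.raises(ValueError, match="uniform"):
            detect_spikes((t, np.zeros(4)))


class TestFeatureValues:
    def test_constant_isis_have_zero_adaptation_and_cv(self):
        times = list(np.arange(120.0, 400.0, 25.0))
        t, v = gaussian_spike_trace(times)
        sp = detect_spikes((t, v))
        fs = extract_features((t, v), sp, (100.0, 450.0))
        assert fs.adaptation_index == pytest.approx(0.0, abs=1e-9)
        assert fs.ISI_CV == pytest.approx(0.0, abs=1e-9)

    def test_two_isis_sample_cv(self):
        # ISIs 8 and 12 ms: sample sd (ddof=1) / mean = 2.828/10
        t, v = gaussian_spike_trace([120.0, 128.0, 140.0])
        sp = detect_spikes((t, v))
        fs = extract_features((t, v), sp, (100.0, 200.0))
        assert fs.ISI_CV == pytest.approx(0.2828, abs=2e-3)

    def test_mean_frequency_last_spike_convention(self):
        t, v = gaussian_spike_trace([150.0, 200.0, 250.0, 300.0])
        sp = detect_spikes((t, v))
        fs = extract_features((t, v), sp, (100.0, 400.0))
        assert fs.mean_frequency == pytest.approx(4 / 0.2, rel=1e-3)
        assert fs.time_to_first_spike == pytest.approx(50.0, abs=0.05)

    def test_single_spike_leaves_isi_features_missing(self):
        t, v = gaussian_spike_trace([150.0])
        sp = detect_spikes((t, v))
        fs = extract_features((t, v), sp, (100.0, 400.0))
        assert math.isnan(fs.ISI_CV)
        assert math.isnan(fs.adaptation_index)
        assert math.isnan(fs.AHP_depth_slow)
        assert not math.isnan(fs.AP_height)

    def test_no_spike_leaves_all_spike_features_missing(self):
        t = np.arange(0, 300, 0.025)
        v = np.full_like(t, -64.0)
        fs = extract_features((t, v), detect_spikes((t, v)), (100.0, 250.0))
        assert fs.resting_voltage == pytest.approx(-64.0)
        assert set(fs.missing()) == set(FEATURE_NAMES) - {"resting_voltage"}


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(0.5, 3.0),
       isis=st.lists(st.floats(5.0, 40.0), min_size=3, max_size=8))
def test_time_rescaling_invariance(scale, isis):
    """ISI_CV and adaptation index are invariant under rescaling time."""
    def feats(isis_ms):
        times = 120.0 + np.cumsum(isis_ms)
        t, v = gaussian_spike_trace(times, total=float(times[-1] + 60))
        sp = detect_spikes((t, v))
        return extract_features((t, v), sp, (100.0, float(times[-1] + 30)))

    a = feats(np.array(isis))
    b = feats(np.array(isis) * scale)
    assert a.ISI_CV == pytest.approx(b.ISI_CV, abs=5e-3)
    assert a.adaptation_index == pytest.approx(b.adaptation_index, abs=5e-3)


def test_extractor_agrees_with_reference_implementation(rng):
    """On random synthetic traces every feature matches an independently
    written implementation of the same definitions."""
    for trial in range(20):
        n = rng.integers(0, 9)
        times = np.sort(150.0 + 700.0 * rng.random(n))
        keep = np.r_[True, np.diff(times) > 4.0] if n else np.array([], bool)
        times = times[keep]
        t, v = gaussian_spike_trace(times, total=1000.0,
                                    rest=-66.0 + rng.normal(0, 1),
                                    amp=90.0 + 10 * rng.random(),
                                    sigma=0.2 + 0.2 * rng.random())
        v += 0.1 * rng.standard_normal(len(v))  # sub-threshold noise
        sp = detect_spikes((t, v))
        fs = extract_features((t, v), sp, (100.0, 900.0))
        ref = ref_features(t, v, 100.0, 900.0)
        for name in FEATURE_NAMES:
            got, want = fs.value(name), ref[name]
            if math.isnan(want):
                assert math.isnan(got), name
            else:
                assert got == pytest.approx(want, abs=1e-6), name


class TestObjectives:
    tmpl = FeatureTemplate({10.0: {"resting_voltage": (-68.5, 12.5),
                                   "mean_frequency": (30.0, 16.2)}})

    def test_exact_match_scores_zero(self):
        fs = FeatureSet(resting_voltage=-68.5, mean_frequency=30.0)
        z = objective_scores({10.0: fs}, self.tmpl)
        assert np.allclose(z, 0.0)

    def test_zscore_hand_value(self):
        fs = FeatureSet(resting_voltage=-64.0, mean_frequency=30.0)
        z = objective_scores({10.0: fs}, self.tmpl)
        assert z[0] == pytest.approx(abs(-64.0 + 68.5) / 12.5)  # 0.36

    def test_missing_feature_scores_penalty(self):
        fs = FeatureSet(resting_voltage=-68.5)  # no spikes
        z = objective_scores({10.0: fs}, self.tmpl)
        assert z[1] == MISSING_PENALTY

    def test_nonnegative_and_zero_iff_match(self):
        fs = FeatureSet(resting_voltage=-60.0, mean_frequency=30.0)
        z = objective_scores({10.0: fs}, self.tmpl)
        assert np.all(z >= 0)
        assert z[0] > 0 and z[1] == 0

    def test_template_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            FeatureTemplate({10.0: {"mean_frequency": (30.0, 0.0)}})

    def test_csv_round_trip(self, tmp_path):
        p = tmp_path / "tmpl.csv"
        self.tmpl.to_csv(p)
        back = FeatureTemplate.from_csv(p)
        assert back.table == self.tmpl.table
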