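"""Spike detection and electrophysiology feature extraction.

Ten features parameterize the granule cell discharge: resting voltage,
AP height/width/half-width, fast and slow AHP depth, time to first
spike, mean frequency, adaptation index and ISI coefficient of
variation.  Each (feature, stimulus amplitude) pair becomes one
optimization objective: the z-scored distance

    z = |feature_model - mean_template| / sd_template

against a template of experimental means and standard deviations.

Conventions (fixed here, applied everywhere):

* detection threshold -20 mV, refractory 1 ms -- granule cell spikes
  peak near +20..+35 mV, so -20 mV separates spikes from subthreshold
  oscillations;
* the per-spike *threshold voltage* is V at which dV/dt first exceeds
  20 mV/ms before the peak; AP width is the time spent above it, and
  half-width the time above the midpoint between threshold and peak;
* fast AHP depth is the absolute voltage minimum within 5 ms after each
  peak; slow AHP depth is the minimum between neighboring spikes with
  the first 5 ms excluded;
* mean frequency uses the last-spike endpoint: N / (t_last - t_onset);
* ISI standard deviation uses the sample convention (ddof = 1);
* features that require spikes (or >= 2 ISIs) are flagged missing when
  undefined, and missing objectives score a fixed penalty of 250, large
  enough to dominate any realistic z-score so that non-spiking
  individuals always rank last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import VoltageTrace

__all__ = ["SpikeTrain", "FeatureSet", "FeatureTemplate", "detect_spikes",
           "extract_features", "objective_scores", "FEATURE_NAMES",
           "MISSING_PENALTY", "DETECTION_THRESHOLD_MV", "REFRACTORY_MS"]

FEATURE_NAMES = (
    "resting_voltage", "AP_height", "AP_width", "AP_half_width",
    "AHP_depth", "AHP_depth_slow", "time_to_first_spike",
    "mean_frequency", "adaptation_index", "ISI_CV",
)

MISSING_PENALTY = 250.0
DETECTION_THRESHOLD_MV = -20.0
REFRACTORY_MS = 1.0
DVDT_THRESHOLD = 20.0  # mV/ms, defines the per-spike threshold voltage
FAST_AHP_WINDOW_MS = 5.0


@dataclass
class SpikeTrain:
    """Detected spikes: peak times (ms, sub-sample refined), peak
    voltages, and per-spike threshold crossing time/voltage."""

    times: np.ndarray
    peak_v: np.ndarray
    threshold_times: np.ndarray
    threshold_v: np.ndarray

    def __post_init__(self):
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.times)

    def isis(self) -> np.ndarray:
        return np.diff(self.times)


@dataclass
class FeatureSet:
    """The ten discharge features for one stimulus amplitude.

    Undefined entries are NaN; ``missing()`` lists them.
    """

    resting_voltage: float = math.nan
    AP_height: float = math.nan
    AP_width: float = math.nan
    AP_half_width: float = math.nan
    AHP_depth: float = math.nan
    AHP_depth_slow: float = math.nan
    time_to_first_spike: float = math.nan
    mean_frequency: float = math.nan
    adaptation_index: float = math.nan
    ISI_CV: float = math.nan
    stimulus_pA: float = math.nan

    def value(self, name: str) -> float:
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FEATURE_NAMES}

    def missing(self) -> list[str]:
        return [n for n in FEATURE_NAMES if math.isnan(getattr(self, n))]


def _parabolic_peak(t: np.ndarray, v: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-sample peak location by parabolic fit through (k-1, k, k+1)."""
    if k <= 0 or k >= len(v) - 1:
        return t[k], v[k]
    y0, y1, y2 = v[k - 1], v[k], v[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return t[k], v[k]
    delta = 0.5 * (y0 - y2) / denom
    dt = t[1] - t[0]
    return t[k] + delta * dt, y1 - 0.25 * (y0 - y2) * delta


def detect_spikes(trace: VoltageTrace | tuple, label: str | None = None,
                  threshold: float = DETECTION_THRESHOLD_MV,
                  refractory: float = REFRACTORY_MS) -> SpikeTrain:
    """Detect spikes as upward threshold crossings on a uniform grid.

    Crossings closer than ``refractory`` to the previous accepted one are
    ignored; each spike's peak is the voltage maximum between its upward
    crossing and the next downward crossing (parabolically refined).
    """
    if isinstance(trace, VoltageTrace):
        if not trace.is_uniform:
            raise ValueError("spike detection requires a uniform time grid")
        t, v = trace.t_ms, trace.voltage(label)
    else:
        t, v = trace
        d = np.diff(t)
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            raise ValueError("spike detection requires a uniform time grid")
    dt = t[1] - t[0]
    above = v >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    down = np.flatnonzero(above[:-1] & ~above[1:]) + 1

    times, peaks, th_t, th_v = [], [], [], []
    last = -np.inf
    dvdt = np.gradient(v, dt)
    for u in up:
        if t[u] - last < refractory:
            continue
        nxt = down[down > u]
        end = nxt[0] if len(nxt) else len(v)
        k = u + int(np.argmax(v[u:end]))
        pt, pv = _parabolic_peak(t, v, k)
        last = t[u]
        times.append(pt)
        peaks.append(pv)
        # threshold voltage: where dV/dt last rises through the
        # threshold before the peak (search back over at most 5 ms)
        j = k
        floor = max(0, k - int(round(5.0 / dt)))
        while j > floor and not (dvdt[j] > DVDT_THRESHOLD
                                 and dvdt[j - 1] <= DVDT_THRESHOLD):
            j -= 1
        th_t.append(t[j])
        th_v.append(v[j])
    return SpikeTrain(np.array(times), np.array(peaks), np.array(th_t),
                      np.array(th_v))


def extract_features(trace: VoltageTrace | tuple, spikes: SpikeTrain,
                     stim_window: tuple[float, float],
                     label: str | None = None,
                     stimulus_pA: float = math.nan) -> FeatureSet:
    """Compute the ten discharge features from one trace.

    ``stim_window`` is (onset, offset) in trace time (ms).  Only spikes
    inside the window contribute.
    """
    if isinstance(trace, VoltageTrace):
        t, v = trace.t_ms, trace.voltage(label)
    else:
        t, v = trace
    onset, offset = stim_window
    fs = FeatureSet(stimulus_pA=stimulus_pA)

    pre = (t >= max(0.0, onset - 100.0)) & (t < onset)
    if pre.any():
        fs.resting_voltage = float(v[pre].mean())

    sel = (spikes.times >= onset) & (spikes.times <= offset)
    st = spikes.times[sel]
    pv = spikes.peak_v[sel]
    tv = spikes.threshold_v[sel]
    if len(st) == 0:
        return fs

    fs.AP_height = float(pv.mean())
    fs.time_to_first_spike = float(st[0] - onset)
    fs.mean_frequency = float(len(st) / (st[-1] - onset) * 1e3)

    dt = t[1] - t[0]
    widths, half_widths, ahp_fast = [], [], []
    for i in range(len(st)):
        k = int(round((st[i] - t[0]) / dt))
        k0, k1 = max(k - 2, 0), min(k + 3, len(v))
        k = k0 + int(np.argmax(v[k0:k1]))  # snap to the local sample maximum
        base = tv[i]
        half = 0.5 * (base + pv[i])
        widths.append(_level_width(t, v, k, base))
        half_widths.append(_level_width(t, v, k, half))
        w = (t > st[i]) & (t <= st[i] + FAST_AHP_WINDOW_MS)
        if w.any():
            ahp_fast.append(v[w].min())
    fs.AP_width = float(np.mean(widths))
    fs.AP_half_width = float(np.mean(half_widths))
    if ahp_fast:
        fs.AHP_depth = float(np.mean(ahp_fast))

    if len(st) >= 2:
        slow = []
        for i in range(len(st) - 1):
            w = (t > st[i] + FAST_AHP_WINDOW_MS) & (t < st[i + 1])
            if w.any():
                slow.append(v[w].min())
        if slow:
            fs.AHP_depth_slow = float(np.mean(slow))
    if len(st) >= 3:
        isi = np.diff(st)
        fs.ISI_CV = float(isi.std(ddof=1) / isi.mean())
        pairs = (isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])
        fs.adaptation_index = float(pairs.mean())
    return fs


def _level_width(t, v, kpeak, level) -> float:
    """Time spent above ``level`` around the peak sample ``kpeak``, with
    linear interpolation at both edges."""
    dt = t[1] - t[0]
    if v[kpeak] <= level:
        return 0.0
    i = kpeak
    while i > 0 and v[i - 1] > level:
        i -= 1
    j = kpeak
    while j < len(v) - 1 and v[j + 1] > level:
        j += 1
    left = t[i]
    if i > 0 and v[i] != v[i - 1]:
        left = t[i] - dt * (v[i] - level) / (v[i] - v[i - 1])
    right = t[j]
    if j < len(v) - 1 and v[j] != v[j + 1]:
        right = t[j] + dt * (v[j] - level) / (v[j] - v[j + 1])
    return right - left


# --------------------------------------------------------------------------
# templates and objectives
# --------------------------------------------------------------------------

@dataclass
class FeatureTemplate:
    """Per-stimulus feature means and standard deviations.

    ``table[stimulus_pA][feature] = (mean, sd)``; sds must be positive
    (objectives normalize by them).
    """

    table: dict[float, dict[str, tuple[float, float]]] = field(
        default_factory=dict)

    def __post_init__(self):
        for stim, feats in self.table.items():
            for name, (mu, sd) in feats.items():
                if sd <= 0:
                    raise ValueError(
                        f"template sd must be > 0 ({name} @ {stim} pA)")

    @property
    def stimuli(self) -> list[float]:
        return sorted(self.table)

    def mean(self, stim: float, feature: str) -> float:
        return self.table[stim][feature][0]

    def sd(self, stim: float, feature: str) -> float:
        return self.table[stim][feature][1]

    @classmethod
    def from_csv(cls, path: str | Path, mean_col: str = "exp_mean",
                 sd_col: str = "exp_sd") -> "FeatureTemplate":
        df = pd.read_csv(path)
        table: dict = {}
        for _, row in df.iterrows():
            stim = float(row["stimulus_pA"])
            table.setdefault(stim, {})[row["feature"]] = (
                float(row[mean_col]), float(row[sd_col]))
        return cls(table)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for stim in self.stimuli:
            for name in FEATURE_NAMES:
                if name in self.table[stim]:
                    mu, sd = self.table[stim][name]
                    rows.append({"feature": name, "stimulus_pA": stim,
                                 "exp_mean": mu, "exp_sd": sd})
        pd.DataFrame(rows).to_csv(path, index=False)


def objective_scores(feature_sets: dict[float, FeatureSet],
                     template: FeatureTemplate,
                     penalty: float = MISSING_PENALTY) -> np.ndarray:
    """Objective vector: one z-score per (feature, stimulus) pair.

    Ordering: stimuli ascending, features in ``FEATURE_NAMES`` order.
    Missing model features score ``penalty``.  Total function: always
    returns a finite vector.
    """
    out = []
    for stim in template.stimuli:
        fs = feature_sets.get(stim)
        for name in FEATURE_NAMES:
            if name not in template.table[stim]:
                continue
            mu, sd = template.table[stim][name]
            val = fs.value(name) if fs is not None else math.nan
            out.append(penalty if math.isnan(val) else abs(val - mu) / sd)
    return np.array(out)
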