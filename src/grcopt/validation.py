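"""Emergent-property validation protocols.

These analyses probe behaviors that were *not* used as optimization
objectives: the frequency/current relation and first-spike delay,
Kir-mediated inward rectification under negative current steps,
theta-band resonance under a ZAP chirp, near-threshold subthreshold
oscillations, action-potential conduction along the ascending axon with
back-propagation into the dendrites, and the deviation of conductance
densities from their experimental reference values.  A model that was
fitted only on discharge features but reproduces these is biophysically
plausible rather than merely curve-fitted.

Every protocol runs on any :class:`CellModel` without reconfiguration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import simulate, simulate_batch, vclamp
from .features import detect_spikes, extract_features
from .morphology import CellModel
from .protocols import (FI_STEP_AMPLITUDES_PA, NEG_STEP_AMPLITUDES_PA,
                        VClampProtocol, step_protocol, zap_cycle_edges,
                        zap_protocol)

__all__ = ["FICurve", "ResonanceCurve", "OscillationReport",
           "PropagationReport", "GmaxDeviation", "fi_curve", "rheobase",
           "inward_rectification", "zap_resonance",
           "near_threshold_oscillations", "conduction_metrics",
           "gmax_deviation", "input_resistance"]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class FICurve:
    amplitudes_pA: np.ndarray
    frequency_hz: np.ndarray          # NaN where silent
    first_spike_delay_ms: np.ndarray  # NaN where silent
    slope_hz_per_pA: float            # least squares over spiking points
    empty: bool = False


@dataclass
class ResonanceCurve:
    input_freq_hz: np.ndarray         # per ZAP cycle
    output_freq_hz: np.ndarray        # mean instantaneous rate per cycle
    mean_isi_ms: np.ndarray
    peak_freq_hz: float
    no_resonance: bool = False


@dataclass
class OscillationReport:
    holding_pA: float
    dominant_freq_hz: float
    amplitude_mV: float
    freq_axis_hz: np.ndarray = field(repr=False, default=None)
    power: np.ndarray = field(repr=False, default=None)


@dataclass
class PropagationReport:
    peak_times_ms: dict[str, float]
    speed_mm_per_ms: float
    backprop_delay_ms: float
    soma_to_axon_mid_delay_ms: float
    degenerate: bool = False  # identical peak times at the two axon sites


@dataclass
class GmaxDeviation:
    names: list[str]
    per_gene_percent: np.ndarray   # mean |model-ref|/ref*100 per gene
    mean_percent: float


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------

def fi_curve(model: CellModel, amplitudes=FI_STEP_AMPLITUDES_PA,
             gvec: np.ndarray | None = None, duration_ms: float = 2000.0,
             dt: float = 0.025, settle_ms: float = 500.0) -> FICurve:
    """Frequency/current relation with first-spike delays.

    Simulates every amplitude in one lock-step batch and fits the
    least-squares line of mean frequency against current over the
    spiking amplitudes.
    """
    amps = np.asarray(sorted(amplitudes), dtype=float)
    if gvec is None:
        gvec = model.reference_vector()
    proto = step_protocol(1.0, duration_ms=duration_ms, pre_ms=100.0,
                          post_ms=20.0)
    t, vmat = simulate_batch(model, np.tile(gvec, (len(amps), 1)), proto,
                             dt=dt, settle_ms=settle_ms, stim_scale=amps)
    freq = np.full(len(amps), np.nan)
    delay = np.full(len(amps), np.nan)
    for i in range(len(amps)):
        sp = detect_spikes((t, vmat[i]))
        fs = extract_features((t, vmat[i]), sp,
                              (100.0, 100.0 + duration_ms))
        freq[i] = fs.mean_frequency
        delay[i] = fs.time_to_first_spike
    ok = np.isfinite(freq)
    if ok.sum() >= 2:
        slope = float(np.polyfit(amps[ok], freq[ok], 1)[0])
        return FICurve(amps, freq, delay, slope)
    return FICurve(amps, freq, delay, math.nan, empty=True)


def rheobase(model: CellModel, gvec: np.ndarray | None = None,
             lo: float = 0.0, hi: float = 30.0, tol: float = 0.5,
             duration_ms: float = 1000.0, dt: float = 0.05,
             settle_ms: float = 400.0) -> float:
    """Minimal step current (pA, +/- ``tol``) eliciting a spike."""
    if gvec is None:
        gvec = model.reference_vector()
    proto = step_protocol(1.0, duration_ms=duration_ms, pre_ms=50.0,
                          post_ms=0.0)

    def spikes_at(amp: float) -> bool:
        t, v = simulate_batch(model, gvec, proto, dt=dt,
                              settle_ms=settle_ms,
                              stim_scale=np.array([amp]))
        return detect_spikes((t, v[0])).n > 0

    if spikes_at(lo):
        return lo
    if not spikes_at(hi):
        return math.inf
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def inward_rectification(model: CellModel,
                         amplitudes=NEG_STEP_AMPLITUDES_PA,
                         gvec: np.ndarray | None = None,
                         duration_ms: float = 3000.0, dt: float = 0.025,
                         settle_ms: float = 1500.0) -> dict:
    """Responses to hyperpolarizing steps and the rectification index.

    The index is the ratio of chord conductance at the largest negative
    amplitude over the smallest; values above 1 indicate the
    supra-ohmic, Kir-mediated increase of conductance with
    hyperpolarization (the responses crowd together as the voltage
    approaches the potassium reversal).  A purely passive model scores
    exactly 1.  The steps are long (seconds) because the inward
    rectifier activates slowly below rest.
    """
    amps = np.asarray(sorted(amplitudes, key=abs), dtype=float)
    if np.any(amps > 0):
        raise ValueError("rectification amplitudes must be negative")
    if gvec is None:
        gvec = model.reference_vector()
    proto = step_protocol(1.0, duration_ms=duration_ms, pre_ms=200.0,
                          post_ms=100.0)
    t, vmat = simulate_batch(model, np.tile(gvec, (len(amps), 1)), proto,
                             dt=dt, settle_ms=settle_ms, stim_scale=amps)
    v_rest = float(vmat[:, t < 200.0].mean())
    ss_win = (t > 200.0 + 0.8 * duration_ms) & (t < 200.0 + duration_ms)
    v_ss, v_peak, chord, anomaly = [], [], [], False
    for i, amp in enumerate(amps):
        v = vmat[i]
        if detect_spikes((t, v)).n > 0:
            anomaly = True
        vss = float(v[ss_win].mean())
        v_ss.append(vss)
        v_peak.append(float(v[(t >= 200.0) & (t <= 200.0 + duration_ms)].min()))
        # chord conductance in nS: pA / mV
        chord.append(abs(amp) / abs(vss - v_rest) if vss != v_rest
                     else math.inf)
    index = chord[-1] / chord[0]
    return {"amplitudes_pA": amps, "v_rest_mV": v_rest,
            "v_steady_mV": np.array(v_ss), "v_peak_mV": np.array(v_peak),
            "chord_nS": np.array(chord),
            "rectification_index": float(index),
            "spike_anomaly": anomaly}


def zap_resonance(model: CellModel, a_pA: float = 10.0,
                  f_max_hz: float = 10.0, duration_ms: float = 30000.0,
                  holding_pA: float | None = None,
                  gvec: np.ndarray | None = None, dt: float = 0.025,
                  settle_ms: float = 500.0,
                  use_mean_isi: bool = False) -> ResonanceCurve:
    """Spike-rate resonance under a 0-10 Hz ZAP chirp.

    The cell is biased just above rheobase (``holding_pA`` defaults to
    rheobase + 2 pA) so it fires throughout the sweep; the instantaneous
    frequency of every adjacent spike pair is averaged within each ZAP
    cycle and plotted against the cycle's input frequency.  The peak of
    that curve is the resonance frequency.  With ``use_mean_isi`` the
    per-cycle mean ISI is used to locate the (inverted) peak instead.
    """
    if gvec is None:
        gvec = model.reference_vector()
    if holding_pA is None:
        holding_pA = rheobase(model, gvec) + 2.0
    proto = zap_protocol(a_pA, f_max_hz, duration_ms, pre_ms=500.0,
                         holding_pA=holding_pA)
    t, vmat = simulate_batch(model, gvec, proto, dt=dt,
                             settle_ms=settle_ms)
    v = vmat[0]
    sp = detect_spikes((t, v))
    st = sp.times[(sp.times >= 500.0) & (sp.times <= 500.0 + duration_ms)]
    if len(st) < 2:
        return ResonanceCurve(np.array([]), np.array([]), np.array([]),
                              math.nan, no_resonance=True)
    st_rel = st - 500.0
    mid = 0.5 * (st_rel[1:] + st_rel[:-1])
    inst = 1e3 / np.diff(st_rel)
    edges = zap_cycle_edges(proto.b_rad_s2, duration_ms)
    b = proto.b_rad_s2
    fin, fout, misi = [], [], []
    for k in range(1, len(edges) - 1):
        in_cycle = (mid >= edges[k]) & (mid < edges[k + 1])
        if not in_cycle.any():
            continue
        t_mid_s = 0.5 * (edges[k] + edges[k + 1]) * 1e-3
        fin.append(b * t_mid_s / np.pi)
        fout.append(float(inst[in_cycle].mean()))
        misi.append(float(np.diff(st_rel)[in_cycle].mean()))
    fin, fout, misi = np.array(fin), np.array(fout), np.array(misi)
    if len(fin) == 0:
        return ResonanceCurve(fin, fout, misi, math.nan, no_resonance=True)
    peak = float(fin[np.argmin(misi)] if use_mean_isi
                 else fin[np.argmax(fout)])
    return ResonanceCurve(fin, fout, misi, peak)


def near_threshold_oscillations(model: CellModel,
                                gvec: np.ndarray | None = None,
                                hold_below_pA: float = 1.0,
                                duration_ms: float = 5000.0,
                                dt: float = 0.05, settle_ms: float = 500.0,
                                max_retries: int = 3) -> OscillationReport:
    """Subthreshold oscillations just below rheobase.

    Holds the cell ``hold_below_pA`` below its rheobase for several
    seconds and locates the dominant spectral peak (above 1 Hz) of the
    mean-removed, Hann-windowed, zero-padded voltage spectrum.  If the
    holding current still elicits spikes the current is lowered one step
    and the protocol retried.
    """
    if gvec is None:
        gvec = model.reference_vector()
    rb = rheobase(model, gvec)
    hold = rb - hold_below_pA
    for _ in range(max_retries + 1):
        proto = step_protocol(hold, duration_ms=duration_ms, pre_ms=100.0,
                              post_ms=0.0)
        t, vmat = simulate_batch(model, gvec, proto, dt=dt,
                                 settle_ms=settle_ms)
        v = vmat[0]
        if detect_spikes((t, v)).n == 0:
            break
        hold -= 1.0
    else:
        raise RuntimeError("could not find a spike-free holding current")
    # discard the first second (charging transient)
    sel = t >= 1000.0
    x = v[sel] - v[sel].mean()
    w = np.hanning(len(x))
    nfft = int(2 ** np.ceil(np.log2(len(x) * 4)))
    spec = np.abs(np.fft.rfft(x * w, nfft))
    freqs = np.fft.rfftfreq(nfft, d=dt * 1e-3)
    band = freqs >= 1.0
    kpk = np.argmax(spec[band])
    dom = float(freqs[band][kpk])
    amp = float(np.ptp(x))
    return OscillationReport(holding_pA=hold, dominant_freq_hz=dom,
                             amplitude_mV=amp, freq_axis_hz=freqs,
                             power=spec**2)


def _path_distance_um(model: CellModel, a: int, b: int) -> float:
    """Mid-to-mid distance (um) along the tree between compartments."""
    def ancestors(i):
        out = [i]
        while model.parents[out[-1]] >= 0:
            out.append(model.parents[out[-1]])
        return out

    def half_len(i):
        c = model.compartments[i]
        return (c.radius_um if c.shape == "sphere" else 0.5 * c.length_um)

    pa, pb = ancestors(a), ancestors(b)
    common = next(x for x in pa if x in pb)
    dist = 0.0
    for path in (pa[:pa.index(common)], pb[:pb.index(common)]):
        for j, i in enumerate(path):
            dist += half_len(i) * (1 if j in (0,) else 2)
        if path:
            dist += half_len(common)
    return dist


def conduction_metrics(model: CellModel, amplitude_pA: float = 16.0,
                       gvec: np.ndarray | None = None,
                       axon_sites: tuple[str, str] = ("axon_3", "axon_13"),
                       dendrite_site: str = "dendrite_1",
                       duration_ms: float = 500.0, dt: float = 0.0125,
                       settle_ms: float = 500.0,
                       spike_index: int = 1) -> PropagationReport:
    """Axonal conduction speed and dendritic back-propagation delay.

    Records every compartment during a somatic step, takes the
    ``spike_index``-th action potential, and compares its
    (parabolically refined) peak times across sites:
    speed = site separation / peak-time difference along the axon;
    back-propagation delay = |AIS peak - dendrite peak|.
    """
    tr = simulate(model, step_protocol(amplitude_pA,
                                       duration_ms=duration_ms,
                                       pre_ms=50.0, post_ms=20.0),
                  record="all", gvec=gvec, dt=dt, settle_ms=settle_ms)
    n_axon = sum(1 for c in model.compartments
                 if c.label.startswith("axon_"))
    mid_site = f"axon_{max(1, round(n_axon / 2))}"
    peaks: dict[str, float] = {}
    for label in ("AIS", "soma", dendrite_site, mid_site, *axon_sites):
        sp = detect_spikes(tr, label=label, threshold=-30.0)
        if sp.n <= spike_index:
            raise RuntimeError(f"no spike {spike_index} at site {label!r}")
        peaks[label] = float(sp.times[spike_index])
    d_ax = _path_distance_um(model, model.comp_index(axon_sites[0]),
                             model.comp_index(axon_sites[1]))
    dt_ax = peaks[axon_sites[1]] - peaks[axon_sites[0]]
    degenerate = dt_ax == 0.0
    speed = math.inf if degenerate else (d_ax * 1e-3) / dt_ax  # mm/ms
    back = abs(peaks[dendrite_site] - peaks["AIS"])
    soma_mid = peaks[mid_site] - peaks["soma"]
    return PropagationReport(peak_times_ms=peaks, speed_mm_per_ms=speed,
                             backprop_delay_ms=back,
                             soma_to_axon_mid_delay_ms=soma_mid,
                             degenerate=degenerate)


def gmax_deviation(genes: np.ndarray, reference: np.ndarray,
                   names: list[str] | None = None) -> GmaxDeviation:
    """Percent deviation of conductance vectors from their reference.

    ``genes`` is (N, G) or (G,).  Per-gene deviations
    |G_model - G_ref| / G_ref * 100 are averaged over individuals first,
    then over genes for the summary mean.
    """
    g = np.atleast_2d(np.asarray(genes, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if g.shape[1] != len(ref):
        raise ValueError("gene/reference length mismatch")
    if np.any(ref == 0):
        raise ValueError("reference contains zeros")
    dev = np.abs(g - ref[None, :]) / np.abs(ref[None, :]) * 100.0
    per_gene = dev.mean(axis=0)
    if names is None:
        names = [f"g{i}" for i in range(len(ref))]
    return GmaxDeviation(list(names), per_gene, float(per_gene.mean()))


def input_resistance(model: CellModel, gvec: np.ndarray | None = None,
                     step_mV: float = -10.0, duration_ms: float = 100.0,
                     dt: float = 0.025,
                     settle_ms: float = 4000.0) -> float:
    """Input resistance (GOhm) from a somatic voltage-clamp transient.

    Clamps the soma at its resting potential, applies ``step_mV`` for
    ``duration_ms``, and divides the command step by the steady-state
    current change.  The long pre-run settle matters: the slow inward
    rectifier takes seconds to equilibrate, and an unsettled baseline
    contaminates the transient.
    """
    proto = VClampProtocol(step_mV=step_mV, onset_ms=50.0,
                           duration_ms=duration_ms, post_ms=20.0)
    t, i_pa, _ = vclamp(model, proto, gvec=gvec, dt=dt,
                        settle_ms=settle_ms)
    base = i_pa[(t > 30.0) & (t < 50.0)].mean()
    ss_lo = 50.0 + 0.9 * duration_ms
    ss = i_pa[(t > ss_lo) & (t < 50.0 + duration_ms)].mean()
    di = ss - base
    if not np.isfinite(di) or di == 0:
        raise RuntimeError("voltage clamp did not converge")
    return float(step_mV / di)  # mV/pA = GOhm
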