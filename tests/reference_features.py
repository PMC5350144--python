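"""Independent reference implementation of the discharge features.

Deliberately written in a plain, loop-heavy style, sharing no code with
grcopt.features: it serves as the oracle in the extractor-agreement
tests.  Definitions:

  resting_voltage  mean V in the 100 ms before stimulus onset
  AP_height        mean of per-spike peak voltages
  AP_width         mean time above the per-spike dV/dt-threshold voltage
  AP_half_width    mean time above (threshold + peak) / 2
  AHP_depth        mean of the V minimum within 5 ms after each peak
  AHP_depth_slow   mean of the V minimum between spikes, first 5 ms
                   excluded
  time_to_first_spike  first peak time minus onset
  mean_frequency   N_spikes / (last peak - onset), in Hz
  adaptation_index mean of (ISI[k+1]-ISI[k])/(ISI[k+1]+ISI[k])
  ISI_CV           sample std (ddof=1) of ISIs over their mean
"""

import numpy as np


def ref_detect(t, v, thresh=-20.0, refractory=1.0, dvdt_thresh=20.0):
    dt = t[1] - t[0]
    dvdt = np.gradient(v, dt)
    peaks = []
    th_v = []
    i = 1
    last_up = -1e9
    while i < len(v):
        if v[i] >= thresh and v[i - 1] < thresh and t[i] - last_up >= refractory:
            last_up = t[i]
            j = i
            while j < len(v) - 1 and v[j + 1] >= thresh:
                j += 1
            seg = v[i:j + 1]
            k = i + int(np.argmax(seg))
            # parabolic refinement identical in definition, reimplemented
            if 0 < k < len(v) - 1:
                y0, y1, y2 = v[k - 1], v[k], v[k + 1]
                den = y0 - 2 * y1 + y2
                if den < 0:
                    d = 0.5 * (y0 - y2) / den
                    peaks.append((t[k] + d * dt,
                                  y1 - 0.25 * (y0 - y2) * d, k))
                else:
                    peaks.append((t[k], v[k], k))
            else:
                peaks.append((t[k], v[k], k))
            m = k
            lo = max(0, k - int(round(5.0 / dt)))
            while m > lo:
                if dvdt[m] > dvdt_thresh and dvdt[m - 1] <= dvdt_thresh:
                    break
                m -= 1
            th_v.append(v[m])
            i = j + 1
        else:
            i += 1
    return peaks, th_v


def _width_above(t, v, kpeak, level):
    if v[kpeak] <= level:
        return 0.0
    dt = t[1] - t[0]
    i = kpeak
    while i > 0 and v[i - 1] > level:
        i -= 1
    j = kpeak
    while j < len(v) - 1 and v[j + 1] > level:
        j += 1
    tl = t[i]
    if i > 0 and v[i] != v[i - 1]:
        tl = t[i] - dt * (v[i] - level) / (v[i] - v[i - 1])
    tr = t[j]
    if j < len(v) - 1 and v[j] != v[j + 1]:
        tr = t[j] + dt * (v[j] - level) / (v[j] - v[j + 1])
    return tr - tl


def ref_features(t, v, onset, offset):
    out = {k: np.nan for k in
           ["resting_voltage", "AP_height", "AP_width", "AP_half_width",
            "AHP_depth", "AHP_depth_slow", "time_to_first_spike",
            "mean_frequency", "adaptation_index", "ISI_CV"]}
    pre = (t >= max(0.0, onset - 100.0)) & (t < onset)
    if pre.any():
        out["resting_voltage"] = float(np.mean(v[pre]))
    peaks, th_v = ref_detect(t, v)
    use = [(pt, pv, k, th) for (pt, pv, k), th in zip(peaks, th_v)
           if onset <= pt <= offset]
    if not use:
        return out
    times = [p[0] for p in use]
    out["AP_height"] = float(np.mean([p[1] for p in use]))
    out["time_to_first_spike"] = times[0] - onset
    out["mean_frequency"] = len(use) / (times[-1] - onset) * 1e3

    widths, halves, fast = [], [], []
    for pt, pv, k, th in use:
        k0 = max(k - 2, 0)
        k = k0 + int(np.argmax(v[k0:min(k + 3, len(v))]))
        widths.append(_width_above(t, v, k, th))
        halves.append(_width_above(t, v, k, 0.5 * (th + pv)))
        w = (t > pt) & (t <= pt + 5.0)
        if w.any():
            fast.append(np.min(v[w]))
    out["AP_width"] = float(np.mean(widths))
    out["AP_half_width"] = float(np.mean(halves))
    if fast:
        out["AHP_depth"] = float(np.mean(fast))
    if len(use) >= 2:
        slow = []
        for a, b in zip(use[:-1], use[1:]):
            w = (t > a[0] + 5.0) & (t < b[0])
            if w.any():
                slow.append(np.min(v[w]))
        if slow:
            out["AHP_depth_slow"] = float(np.mean(slow))
    if len(use) >= 3:
        isi = np.diff(times)
        out["ISI_CV"] = float(np.std(isi, ddof=1) / np.mean(isi))
        ai = [(isi[k + 1] - isi[k]) / (isi[k + 1] + isi[k])
              for k in range(len(isi) - 1)]
        out["adaptation_index"] = float(np.mean(ai))
    return out
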