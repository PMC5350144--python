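"""Stimulation protocols: current steps, ZAP chirps, voltage clamp.

Step amplitudes follow the experimental design: {10, 16, 22} pA for
optimization templates, 10..34 pA in 6 pA increments and -3..-9 pA in
3 pA increments for validation.  The ZAP chirp is
``I(t) = A sin(B t^2)`` with amplitude A = 10 pA and sweep constant B
chosen so the instantaneous frequency ``f(t) = B t / pi`` covers
0-10 Hz over the protocol duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusProtocol", "VClampProtocol", "step_protocol",
           "zap_protocol", "zap_current", "zap_cycle_edges",
           "OPT_STEP_AMPLITUDES_PA", "FI_STEP_AMPLITUDES_PA",
           "NEG_STEP_AMPLITUDES_PA"]

OPT_STEP_AMPLITUDES_PA = (10.0, 16.0, 22.0)
FI_STEP_AMPLITUDES_PA = (10.0, 16.0, 22.0, 28.0, 34.0)
NEG_STEP_AMPLITUDES_PA = (-3.0, -6.0, -9.0)


def zap_current(a_pA: float, b_rad_s2: float, t_ms):
    """ZAP waveform ``A sin(B t^2)`` (pA); ``B`` in rad/s^2, t in ms.

    The instantaneous frequency is ``f(t) = B t / pi`` (Hz, t in s), a
    linear sweep; zero crossings sit at ``t_k = sqrt(k pi / B)``.
    """
    t_s = np.asarray(t_ms, dtype=float) * 1e-3
    if np.any(t_s < 0):
        raise ValueError("negative time in ZAP evaluation")
    return a_pA * np.sin(b_rad_s2 * t_s**2)


def zap_cycle_edges(b_rad_s2: float, duration_ms: float) -> np.ndarray:
    """Times (ms) of the full-period boundaries t_k = sqrt(2 pi k / B)."""
    d_s = duration_ms * 1e-3
    kmax = int(np.floor(b_rad_s2 * d_s**2 / (2 * np.pi)))
    k = np.arange(kmax + 1)
    return np.sqrt(2 * np.pi * k / b_rad_s2) * 1e3


@dataclass(frozen=True)
class StimulusProtocol:
    """Current-injection protocol.

    ``kind`` is ``"step"`` or ``"zap"``.  ``holding_pA`` is a tonic offset
    applied for the whole trace (used to bias the cell just above rheobase
    during resonance runs).  ``injection_site`` is a compartment label.
    """

    kind: str
    onset_ms: float
    offset_ms: float
    amplitude_pA: float
    total_ms: float
    b_rad_s2: float = 0.0
    holding_pA: float = 0.0
    injection_site: str = "soma"

    def __post_init__(self):
        if self.kind not in ("step", "zap"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")
        if self.kind == "zap" and self.b_rad_s2 <= 0:
            raise ValueError("zap protocol needs a positive sweep constant")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def current_pA(self, t_ms) -> np.ndarray:
        """Injected current (pA) on a time grid (ms)."""
        t = np.asarray(t_ms, dtype=float)
        i = np.full(t.shape, self.holding_pA)
        inside = (t >= self.onset_ms) & (t < self.offset_ms)
        if self.kind == "step":
            i[inside] += self.amplitude_pA
        else:
            i[inside] += zap_current(self.amplitude_pA, self.b_rad_s2,
                                     t[inside] - self.onset_ms)
        return i


@dataclass(frozen=True)
class VClampProtocol:
    """Somatic voltage clamp: hold at rest, then step by ``step_mV``."""

    step_mV: float = -10.0
    onset_ms: float = 50.0
    duration_ms: float = 100.0
    post_ms: float = 20.0
    site: str = "soma"

    @property
    def total_ms(self) -> float:
        return self.onset_ms + self.duration_ms + self.post_ms


def step_protocol(amplitude_pA: float, duration_ms: float = 2000.0,
                  pre_ms: float = 100.0, post_ms: float = 50.0,
                  holding_pA: float = 0.0,
                  injection_site: str = "soma") -> StimulusProtocol:
    """Square current step with a pre-stimulus baseline window."""
    return StimulusProtocol("step", pre_ms, pre_ms + duration_ms,
                            amplitude_pA, pre_ms + duration_ms + post_ms,
                            holding_pA=holding_pA,
                            injection_site=injection_site)


def zap_protocol(a_pA: float = 10.0, f_max_hz: float = 10.0,
                 duration_ms: float = 30000.0, pre_ms: float = 100.0,
                 holding_pA: float = 0.0,
                 injection_site: str = "soma") -> StimulusProtocol:
    """ZAP sweep 0 -> ``f_max_hz`` over ``duration_ms``.

    The sweep constant follows from f(t) = B t / pi at t = duration.
    """
    d_s = duration_ms * 1e-3
    b = np.pi * f_max_hz / d_s
    return StimulusProtocol("zap", pre_ms, pre_ms + duration_ms, a_pA,
                            pre_ms + duration_ms + 50.0, b_rad_s2=b,
                            holding_pA=holding_pA,
                            injection_site=injection_site)
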