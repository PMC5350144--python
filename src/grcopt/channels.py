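"""Voltage- and calcium-dependent membrane mechanisms.

The granule cell membrane carries nine active conductances (Na, Nap, Nar,
KV, KA, Kslow, Kir, KCa, Ca-HVA) plus an ohmic leak and a sub-membrane
calcium shell.  Channels are represented either in Hodgkin-Huxley style --
independent gating particles with voltage-dependent rates, conductance
``gmax * prod(m_k^p_k)`` -- or as a Markov kinetic scheme whose open-state
occupancy scales the conductance (used for the resurgent sodium channel of
the multi-compartment model).

Sign convention: positive current is outward.  Inward currents (Na, Ca,
Kir below E_K) are negative.  This convention is applied everywhere in the
package.

All gating kinetics are stored already normalized to 30 degC; no Q10
scaling is applied at simulation time (see :mod:`grcopt.kinetics`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    CA_VALENCE,
    FARADAY,
    GAS_CONSTANT,
    KINETICS_TEMP_C,
    celsius_to_kelvin,
)

__all__ = [
    "RateFn",
    "GateSpec",
    "HHChannelSpec",
    "MarkovChannelSpec",
    "CalciumPool",
    "gate_steady_state",
    "channel_current",
    "markov_step",
    "update_calcium",
    "calcium_reversal",
    "resurgent_na_13state",
]


# --------------------------------------------------------------------------
# rate functions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateFn:
    """One voltage-dependent rate or steady-state curve.

    kind:
      - ``exp``      a * exp((V - v0) / k)
      - ``sigmoid``  a / (1 + exp((V - v0) / k))
      - ``linoid``   a * (V - v0) / (exp((V - v0) / k) - 1), with the
                     removable singularity at V = v0 filled by its limit
                     ``-a * k``
      - ``constant`` a
      - ``bell``     a / (exp((V - v0) / k) + exp(-(V - v0) / k2)),
                     the standard peaked time-constant curve
      - ``mlkca``    Moczydlowski-Latorre calcium-dependent rate, see
                     :meth:`__call__`; ``a`` is the saturating rate, ``v0``
                     the reference Ca level (mM) and ``k`` the voltage
                     e-fold (mV); direction set by ``sign``.
    """

    kind: str
    a: float
    v0: float = 0.0
    k: float = 1.0
    k2: float = 1.0
    sign: int = +1  # mlkca only: +1 opening-style, -1 closing-style

    def __call__(self, v, ca=None):
        v = np.asarray(v, dtype=float)
        if self.kind == "exp":
            return self.a * np.exp((v - self.v0) / self.k)
        if self.kind == "sigmoid":
            return self.a / (1.0 + np.exp((v - self.v0) / self.k))
        if self.kind == "bell":
            x = v - self.v0
            return self.a / (np.exp(x / self.k) + np.exp(-x / self.k2))
        if self.kind == "linoid":
            x = (v - self.v0) / self.k
            # limit a*(V-v0)/(exp(x)-1) -> -a*k as x -> 0
            with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
                out = self.a * (v - self.v0) / np.expm1(x)
            out = np.where(np.abs(x) < 1e-7, -self.a * self.k, out)
            return out
        if self.kind == "constant":
            return np.broadcast_to(np.float64(self.a), v.shape).copy() if v.ndim else float(self.a)
        if self.kind == "mlkca":
            if ca is None:
                raise ValueError("mlkca rate requires a calcium concentration")
            ca = np.asarray(ca, dtype=float)
            if self.sign > 0:
                return self.a / (1.0 + (self.v0 / ca) * np.exp(-v / self.k))
            return self.a / (1.0 + (ca / self.v0) * np.exp(v / self.k))
        raise ValueError(f"unknown rate kind {self.kind!r}")


# --------------------------------------------------------------------------
# HH gates and channels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gating particle.

    Either ``alpha``/``beta`` rates or ``minf``/``tau`` curves must be
    given.  ``exponent`` is the particle multiplicity p in m^p.
    ``ca_dependent`` marks gates whose rates take [Ca]i as a second
    argument (KCa).  ``temp_c`` records the temperature the rates are
    normalized to; it is asserted against the kinetics-set reference to
    prevent silent double temperature scaling.
    """

    name: str
    exponent: int = 1
    alpha: RateFn | None = None
    beta: RateFn | None = None
    minf: RateFn | None = None
    tau: RateFn | None = None
    tau_min: float = 0.0  # floor added to tau (ms)
    ca_dependent: bool = False
    temp_c: float = KINETICS_TEMP_C

    def __post_init__(self):
        has_ab = self.alpha is not None and self.beta is not None
        has_it = self.minf is not None and self.tau is not None
        if not (has_ab or has_it):
            raise ValueError(f"gate {self.name!r}: needs alpha/beta or minf/tau")
        if self.exponent < 1:
            raise ValueError(f"gate {self.name!r}: exponent must be >= 1")


def gate_steady_state(gate: GateSpec, v, ca=None):
    """Steady state and time constant of a gate at voltage ``v`` (mV).

    Returns ``(m_inf, tau_ms)`` with ``0 <= m_inf <= 1`` and ``tau > 0``.
    For calcium-dependent gates ``ca`` (mM) must be supplied.
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite voltage passed to gate_steady_state")
    if gate.ca_dependent and ca is None:
        raise ValueError(f"gate {gate.name!r} is calcium dependent; pass ca=")
    kw = {"ca": ca} if gate.ca_dependent else {}
    if gate.alpha is not None:
        a = gate.alpha(v, **kw)
        b = gate.beta(v, **kw)
        denom = a + b
        minf = a / denom
        tau = 1.0 / denom + gate.tau_min
    else:
        minf = gate.minf(v, **kw)
        tau = gate.tau(v, **kw) + gate.tau_min
    minf = np.clip(minf, 0.0, 1.0)
    return minf, tau


@dataclass(frozen=True)
class HHChannelSpec:
    """An HH-style channel placed on one compartment.

    ``gmax`` in mS/cm^2; ``erev`` in mV, or the string ``"ca"`` for a
    reversal potential recomputed from the local calcium pool each step.
    """

    name: str
    gates: tuple[GateSpec, ...]
    gmax: float
    erev: float | str
    compartment: str = "soma"

    def __post_init__(self):
        if self.gmax < 0:
            raise ValueError(f"channel {self.name!r}: gmax must be >= 0")

    def open_fraction(self, gate_states):
        gate_states = np.asarray(gate_states, dtype=float)
        if np.any(gate_states < 0) or np.any(gate_states > 1):
            raise ValueError("gate state outside [0, 1]")
        exps = np.array([g.exponent for g in self.gates], dtype=float)
        if gate_states.shape[-1] != len(self.gates):
            raise ValueError("gate state count does not match channel gates")
        return np.prod(gate_states**exps, axis=-1)


def channel_current(spec: HHChannelSpec, gate_states, v, erev=None):
    """Ohmic current density of one channel, mA/cm^2 (outward positive).

    ``I = gmax * prod(m_k^p_k) * (V - E_rev) * 1e-3`` (mS/cm^2 * mV gives
    uA/cm^2, hence the factor).  ``erev`` overrides the spec value (used
    for the dynamic calcium reversal).
    """
    e = erev if erev is not None else spec.erev
    if isinstance(e, str):
        raise ValueError("dynamic reversal: pass erev= explicitly")
    po = spec.open_fraction(gate_states) if spec.gates else 1.0
    return spec.gmax * po * (np.asarray(v, dtype=float) - e) * 1e-3


# --------------------------------------------------------------------------
# Markov channels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkovChannelSpec:
    """A channel as a continuous-time Markov scheme.

    ``states`` are labels; ``transitions`` is a tuple of
    ``(i, j, RateFn)`` giving the rate from state i to state j (1/ms).
    ``open_states`` indexes the conducting state(s).
    """

    name: str
    states: tuple[str, ...]
    transitions: tuple[tuple[int, int, RateFn], ...]
    open_states: tuple[int, ...]
    gmax: float
    erev: float
    compartment: str = "soma"

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rate_matrix(self, v: float) -> np.ndarray:
        """Generator matrix Q(V); rows sum to zero, Q[i, j] = rate i->j."""
        n = self.n_states
        q = np.zeros((n, n))
        for i, j, fn in self.transitions:
            q[i, j] += float(fn(v))
        q[np.diag_indices(n)] -= q.sum(axis=1)
        return q

    def equilibrium(self, v: float) -> np.ndarray:
        """Stationary distribution at fixed voltage (null space of Q^T)."""
        q = self.rate_matrix(v)
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        p, *_ = np.linalg.lstsq(a, b, rcond=None)
        p = np.clip(p, 0.0, None)
        return p / p.sum()

    def open_fraction(self, occupancy) -> float:
        occupancy = np.asarray(occupancy, dtype=float)
        return occupancy[..., list(self.open_states)].sum(axis=-1)


def markov_step(spec: MarkovChannelSpec, occupancy, v: float, dt: float,
                max_rate_dt: float = 0.1, tol: float = 1e-9):
    """Advance the occupancy distribution by ``dt`` (forward scheme).

    Integrates the master equation dP/dt = P Q(V) with a forward update,
    sub-stepping so that ``max |rate| * dt_sub <= max_rate_dt``; this keeps
    the update a proper stochastic matrix row-wise and preserves total
    occupancy exactly.  Raises if a negative occupancy beyond ``tol``
    appears (caller should reduce dt).
    """
    p = np.asarray(occupancy, dtype=float).copy()
    if dt <= 0:
        raise ValueError("dt must be positive")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("occupancy does not sum to 1")
    q = spec.rate_matrix(v)
    rmax = float(np.abs(q).max())
    nsub = max(1, int(math.ceil(rmax * dt / max_rate_dt)))
    m = np.eye(spec.n_states) + q * (dt / nsub)
    for _ in range(nsub):
        p = p @ m
    if np.any(p < -tol):
        raise FloatingPointError(
            f"negative occupancy after markov step (min {p.min():.3e}); reduce dt")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def resurgent_na_13state(params: dict | None = None) -> dict:
    """Transition table of the unified 13-state resurgent Na channel.

    States: closed C1-C5, open O, open-blocked OB, inactivated I1-I6.
    Activation walks C1..C5 with forward rate (5-n)*alpha(V) and backward
    n*beta(V); C5<->O via gamma/delta; the open state can be blocked
    (O<->OB, epsilon/zeta(V)) -- unbinding of the blocking particle on
    repolarization produces the resurgent current -- or inactivate
    (O<->I6, Oon/Ooff).  Closed states inactivate with Con*a^n / recover
    with Coff*b^n, where a=(Oon/Con)^(1/4), b=(Ooff/Coff)^(1/4) keep the
    scheme thermodynamically consistent; I1..I5<->I6 mirror the activation
    ladder scaled by a and b.

    Returns ``{"states": [...], "transitions": [(i, j, RateFn), ...],
    "open_states": (5,)}`` suitable for :class:`MarkovChannelSpec`.
    """
    p = {
        "alpha": 150.0, "alpha_vdep": 20.0,   # 1/ms, mV e-fold
        "beta": 3.0, "beta_vdep": -20.0,
        "gamma": 150.0, "delta": 40.0,
        "epsilon": 1.75, "zeta": 0.03, "zeta_vdep": -25.0,
        "con": 0.005, "coff": 0.5, "oon": 0.75, "ooff": 0.005,
    }
    if params:
        p.update(params)
    a_fac = (p["oon"] / p["con"]) ** 0.25
    b_fac = (p["ooff"] / p["coff"]) ** 0.25

    states = ["C1", "C2", "C3", "C4", "C5", "O", "OB",
              "I1", "I2", "I3", "I4", "I5", "I6"]
    idx = {s: i for i, s in enumerate(states)}

    def exp_rate(base, vdep):
        return RateFn("exp", base, 0.0, vdep)

    def const(x):
        return RateFn("constant", x)

    trans: list[tuple[int, int, RateFn]] = []
    # activation ladder, closed states
    for n in range(4):  # C1->C2 ... C4->C5
        fwd = 4 - n
        bwd = n + 1
        trans.append((idx[f"C{n+1}"], idx[f"C{n+2}"],
                      exp_rate(fwd * p["alpha"], p["alpha_vdep"])))
        trans.append((idx[f"C{n+2}"], idx[f"C{n+1}"],
                      exp_rate(bwd * p["beta"], p["beta_vdep"])))
    # opening
    trans.append((idx["C5"], idx["O"], const(p["gamma"])))
    trans.append((idx["O"], idx["C5"], const(p["delta"])))
    # open-channel block (resurgence)
    trans.append((idx["O"], idx["OB"], const(p["epsilon"])))
    trans.append((idx["OB"], idx["O"], exp_rate(p["zeta"], p["zeta_vdep"])))
    # inactivation from closed states
    for n in range(5):
        trans.append((idx[f"C{n+1}"], idx[f"I{n+1}"],
                      const(p["con"] * a_fac**n)))
        trans.append((idx[f"I{n+1}"], idx[f"C{n+1}"],
                      const(p["coff"] * b_fac**n)))
    # inactivated ladder
    for n in range(4):
        fwd = 4 - n
        bwd = n + 1
        trans.append((idx[f"I{n+1}"], idx[f"I{n+2}"],
                      exp_rate(fwd * p["alpha"] * a_fac, p["alpha_vdep"])))
        trans.append((idx[f"I{n+2}"], idx[f"I{n+1}"],
                      exp_rate(bwd * p["beta"] * b_fac, p["beta_vdep"])))
    # I5 <-> I6 mirrors C5 <-> O
    trans.append((idx["I5"], idx["I6"], const(p["gamma"] * a_fac)))
    trans.append((idx["I6"], idx["I5"], const(p["delta"] * b_fac)))
    # open-state inactivation
    trans.append((idx["O"], idx["I6"], const(p["oon"])))
    trans.append((idx["I6"], idx["O"], const(p["ooff"])))

    return {"states": tuple(states), "transitions": tuple(trans),
            "open_states": (idx["O"],)}


# --------------------------------------------------------------------------
# calcium pool
# --------------------------------------------------------------------------

#: concentration floor (mM) preventing log-domain blowup in the reversal
CA_FLOOR_MM = 1e-6


@dataclass(frozen=True)
class CalciumPool:
    """First-order sub-membrane calcium shell.

    d[Ca]/dt = -I_Ca / (z F d) - beta_ca ([Ca]i - [Ca]rest)

    with ``d`` the shell depth (um) and ``beta_ca`` ("Calc") the decay rate
    (1/ms).  Inward calcium current (negative by the package sign
    convention) raises [Ca]i.
    """

    ca_mM: float = 1e-4
    ca_rest_mM: float = 1e-4
    ca_out_mM: float = 2.0
    beta_ca: float = 1.5       # 1/ms
    shell_depth_um: float = 0.2
    temp_c: float = KINETICS_TEMP_C

    def influx_coeff(self) -> float:
        """mM/ms per (mA/cm^2) of inward current.

        I (mA/cm^2) over a shell of depth d (um): mol per ms per cm^2 is
        I*1e-3/F/z/1e3; shell volume per cm^2 is d*1e-4 cm^3 = d*1e-7 L.
        """
        d_cm = self.shell_depth_um * 1e-4
        # (A/cm^2) / (C/mol) / cm -> mol/(cm^3 s); * 1e3 -> mol/L/s = M/s
        # * 1e3 -> mM/s; * 1e-3 -> mM/ms.  Combined with I in mA: * 1e-3.
        return 1e-3 / (CA_VALENCE * FARADAY * d_cm) * 1e3


def update_calcium(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance [Ca]i by ``dt`` (ms) under calcium current ``i_ca`` (mA/cm^2).

    Uses the exact exponential update of the linear shell ODE; clamps at
    the configured floor (with a warning) if the update would drive the
    concentration non-positive.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = pool.influx_coeff()
    # dCa/dt = -k*I - beta*(Ca - rest);  fixed point:
    ca_inf = pool.ca_rest_mM - k * i_ca / pool.beta_ca
    ca = ca_inf + (pool.ca_mM - ca_inf) * math.exp(-pool.beta_ca * dt)
    if ca < CA_FLOOR_MM:
        warnings.warn("calcium concentration clamped at floor", RuntimeWarning)
        ca = CA_FLOOR_MM
    return replace(pool, ca_mM=ca)


def calcium_reversal(pool: CalciumPool) -> float:
    """Calcium equilibrium potential (mV), Nernst with dynamic [Ca]i.

    E_Ca = (R T / z F) ln([Ca]o / [Ca]i); recomputed every step during
    simulation so depolarization-driven calcium entry lowers the driving
    force.
    """
    if pool.ca_mM <= 0 or pool.ca_out_mM <= 0:
        raise ValueError("concentrations must be positive")
    t_k = celsius_to_kelvin(pool.temp_c)
    return (GAS_CONSTANT * t_k / (CA_VALENCE * FARADAY)
            * math.log(pool.ca_out_mM / pool.ca_mM) * 1e3)
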