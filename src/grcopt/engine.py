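"""Membrane-equation integration.

Each compartment obeys

    Cm dV/dt = -sum_i g_i(t, V) (V - E_i) + I_axial + I_inj

with the ionic conductances g_i driven by HH gating particles, by the
open-state occupancy of a Markov scheme, or constant (leak).  The default
solver is a fixed-step scheme on a 0.025 ms grid, chosen for bit-level
reproducibility of optimization runs:

* gating particles advance by exponential Euler on tabulated
  ``m_inf(V)``/``tau(V)`` curves (exact for frozen voltage);
* Markov occupancies advance by a precomputed ``expm(Q(V) dt)`` lookup
  table, which is unconditionally stable and conserves total occupancy to
  machine precision;
* voltages advance by a theta-method (Crank-Nicolson by default) solve of
  the compartment-coupled linear system, so the stiff axial and spike
  conductances never limit the step.

The integrator is vectorized over a *population* of conductance vectors:
``simulate_batch`` advances every individual of an optimization
generation in lock-step, which is what makes desk-scale evolutionary runs
practical.  An adaptive stiff solver (LSODA via scipy) is available for
convergence checks through ``solver="adaptive"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .channels import CA_FLOOR_MM, MarkovChannelSpec, gate_steady_state, resurgent_na_13state
from .constants import CA_VALENCE, FARADAY, GAS_CONSTANT, celsius_to_kelvin
from .morphology import CellModel
from .protocols import StimulusProtocol, VClampProtocol
from .trace import VoltageTrace

__all__ = ["simulate", "simulate_batch", "vclamp", "CompiledModel",
           "compile_model"]

V_MIN, V_MAX = -150.0, 80.0
V_STEP = 0.05          # HH gate tables (mV)
V_STEP_MARKOV = 0.1    # Markov propagator tables (mV)
DEFAULT_DT = 0.025     # ms
SETTLE_DT = 0.1        # ms, pre-run at rest
DEFAULT_SETTLE_MS = 500.0


def _nernst_ca(ca_mM, ca_out_mM, temp_c):
    t_k = celsius_to_kelvin(temp_c)
    return (GAS_CONSTANT * t_k / (CA_VALENCE * FARADAY)
            * np.log(ca_out_mM / ca_mM) * 1e3)


# --------------------------------------------------------------------------
# compilation
# --------------------------------------------------------------------------

@dataclass
class _Tables:
    """Per-dt stacked gate tables and Markov propagators."""

    dt: float
    minf: np.ndarray      # [n_tab, nV]
    expf: np.ndarray      # [n_tab, nV]  exp(-dt/tau)
    markov: dict          # entry index -> [nVm, S, S]


class CompiledModel:
    """Flattened, table-driven form of a :class:`CellModel`."""

    def __init__(self, model: CellModel):
        self.model = model
        n = model.n_comp
        self.n = n
        self.areas = model.areas_cm2()                        # cm^2
        self.cm = np.array([c.cm_uf_cm2 for c in model.compartments]) * self.areas  # uF
        gax = model.axial_matrix_uS() * 1e-3                  # mS
        self.lap = np.diag(gax.sum(axis=1)) - gax             # mS, Laplacian
        self.v_grid = np.arange(V_MIN, V_MAX + V_STEP / 2, V_STEP)
        self.vm_grid = np.arange(V_MIN, V_MAX + V_STEP_MARKOV / 2,
                                 V_STEP_MARKOV)

        # ---- flatten channel instances -------------------------------
        hh_comp, hh_gene, hh_gfix, hh_erev, hh_entry = [], [], [], [], []
        gate_specs = []          # unique tabulated gates
        gate_rows = []           # per gate instance: row in table stack
        gate_comp, gate_chan, gate_expo = [], [], []
        kca_comp, kca_chan, kca_gate = [], [], []
        mk_comp, mk_gene, mk_gfix, mk_erev, mk_spec = [], [], [], [], []
        self.markov_specs = []

        gene_counter = 0
        self.gene_ranges = model.parameter_ranges()
        gene_index_of_entry = {}
        for ei, ch in enumerate(model.channels):
            if ch.gmax_range is not None:
                gene_index_of_entry[ei] = gene_counter
                gene_counter += 1
        self.n_genes = len(self.gene_ranges)
        self.calc_gene = (self.n_genes - 1
                          if (model.calcium and model.calcium.optimize_beta)
                          else -1)

        for ei, ch in enumerate(model.channels):
            gene = gene_index_of_entry.get(ei, -1)
            if ch.kind == "markov13":
                spec = MarkovChannelSpec(
                    name=ch.name, gmax=ch.gmax, erev=float(ch.erev),
                    **resurgent_na_13state(ch.markov_params))
                for c in ch.comp_indices:
                    mk_comp.append(c)
                    mk_gene.append(gene)
                    mk_gfix.append(ch.gmax)
                    mk_erev.append(float(ch.erev))
                    mk_spec.append(len(self.markov_specs))
                self.markov_specs.append(spec)
                continue
            for c in ch.comp_indices:
                ci = len(hh_comp)
                hh_comp.append(c)
                hh_gene.append(gene)
                hh_gfix.append(ch.gmax)
                hh_erev.append(np.nan if ch.erev == "ca" else float(ch.erev))
                hh_entry.append(ei)
                for g in ch.gates:
                    if g.ca_dependent:
                        kca_comp.append(c)
                        kca_chan.append(ci)
                        kca_gate.append(g)
                    else:
                        try:
                            row = gate_specs.index(g)
                        except ValueError:
                            gate_specs.append(g)
                            row = len(gate_specs) - 1
                        gate_rows.append(row)
                        gate_comp.append(c)
                        gate_chan.append(ci)
                        gate_expo.append(float(g.exponent))

        self.hh_comp = np.array(hh_comp, dtype=int)
        self.hh_gene = np.array(hh_gene, dtype=int)
        self.hh_gfix = np.array(hh_gfix, dtype=float)
        self.hh_erev = np.array(hh_erev, dtype=float)
        self.hh_entry = np.array(hh_entry, dtype=int)
        self.nc = len(hh_comp)
        self.gate_specs = gate_specs
        self.gate_rows = np.array(gate_rows, dtype=int)
        self.gate_comp = np.array(gate_comp, dtype=int)
        self.gate_chan = np.array(gate_chan, dtype=int)
        self.gate_expo = np.array(gate_expo, dtype=float)
        self.ng = len(gate_rows)

        # sort gate instances by owning channel for grouped products
        order = np.argsort(self.gate_chan, kind="stable")
        for name in ("gate_rows", "gate_comp", "gate_chan", "gate_expo"):
            setattr(self, name, getattr(self, name)[order])
        if self.ng:
            chan_sorted = self.gate_chan
            starts = np.flatnonzero(np.r_[True, np.diff(chan_sorted) != 0])
            self.gate_group_starts = starts
            self.gate_group_chan = chan_sorted[starts]
        else:
            self.gate_group_starts = np.zeros(0, dtype=int)
            self.gate_group_chan = np.zeros(0, dtype=int)

        self.kca_comp = np.array(kca_comp, dtype=int)
        self.kca_chan = np.array(kca_chan, dtype=int)
        self.kca_gates = kca_gate
        self.nkca = len(kca_comp)

        self.mk_comp = np.array(mk_comp, dtype=int)
        self.mk_gene = np.array(mk_gene, dtype=int)
        self.mk_gfix = np.array(mk_gfix, dtype=float)
        self.mk_erev = np.array(mk_erev, dtype=float)
        self.mk_spec = np.array(mk_spec, dtype=int)
        self.nm = len(mk_comp)

        # incidence matrices channel-instance -> compartment
        self.minc = np.zeros((self.nc, n))
        self.minc[np.arange(self.nc), self.hh_comp] = 1.0
        self.minc_m = np.zeros((self.nm, n))
        if self.nm:
            self.minc_m[np.arange(self.nm), self.mk_comp] = 1.0

        # ---- calcium pools -------------------------------------------
        ca = model.calcium
        if ca is not None:
            self.pool_comp = np.array(ca.comp_indices, dtype=int)
            self.np_pool = len(ca.comp_indices)
            self.pool = ca.pool
            slot_of_comp = {c: s for s, c in enumerate(ca.comp_indices)}
            self.ca_chan = np.array(
                [i for i in range(self.nc)
                 if np.isnan(self.hh_erev[i]) and hh_comp[i] in slot_of_comp],
                dtype=int)
            self.ca_chan_pool = np.array(
                [slot_of_comp[hh_comp[i]] for i in self.ca_chan], dtype=int)
            self.kca_pool = np.array(
                [slot_of_comp[c] for c in kca_comp], dtype=int)
        else:
            self.pool_comp = np.zeros(0, dtype=int)
            self.np_pool = 0
            self.pool = None
            self.ca_chan = np.zeros(0, dtype=int)
            self.ca_chan_pool = np.zeros(0, dtype=int)
            self.kca_pool = np.zeros(0, dtype=int)
        if np.isnan(self.hh_erev).any() and self.pool is None:
            raise ValueError("a channel uses the calcium reversal but the "
                             "model defines no calcium pool")

        self.mk_open = (list(self.markov_specs[0].open_states)
                        if self.markov_specs else [])
        # cached Moczydlowski-Latorre parameters for the KCa gates
        self._kca_params = []
        for g in self.kca_gates:
            a, b = g.alpha, g.beta
            self._kca_params.append((a.a, a.v0, a.k, b.a, b.v0, b.k))
        self._tables: dict[float, _Tables] = {}

    # -- tables ------------------------------------------------------------

    def tables(self, dt: float) -> _Tables:
        key = round(dt, 9)
        if key in self._tables:
            return self._tables[key]
        nv = len(self.v_grid)
        minf = np.empty((len(self.gate_specs), nv))
        expf = np.empty((len(self.gate_specs), nv))
        for r, g in enumerate(self.gate_specs):
            mi, tau = gate_steady_state(g, self.v_grid)
            minf[r] = mi
            expf[r] = np.exp(-dt / tau)
        markov = {}
        for si, spec in enumerate(self.markov_specs):
            mats = np.empty((len(self.vm_grid), spec.n_states, spec.n_states))
            for k, v in enumerate(self.vm_grid):
                mats[k] = expm(spec.rate_matrix(v) * dt)
            markov[si] = mats
        t = _Tables(dt=dt, minf=minf, expf=expf, markov=markov)
        self._tables[key] = t
        return t

    # -- state -------------------------------------------------------------

    def init_state(self, batch: int, gvec: np.ndarray) -> dict:
        """Steady-state initialization at the configured resting potential."""
        v0 = self.model.v_init
        st = {
            "v": np.full((batch, self.n), v0),
            "m": np.empty((batch, self.ng)),
            "kca": np.empty((batch, self.nkca)),
            "P": np.empty((batch, self.nm, 13)) if self.nm else
                 np.zeros((batch, 0, 13)),
            "ca": np.full((batch, self.np_pool),
                          self.pool.ca_rest_mM if self.pool else 0.0),
            "gvec": np.asarray(gvec, dtype=float).reshape(batch, -1),
        }
        for k, r in enumerate(self.gate_rows):
            mi, _ = gate_steady_state(self.gate_specs[r], v0)
            st["m"][:, k] = mi
        for k, g in enumerate(self.kca_gates):
            mi, _ = gate_steady_state(g, v0, ca=self.pool.ca_rest_mM)
            st["kca"][:, k] = mi
        for k in range(self.nm):
            st["P"][:, k, :] = self.markov_specs[self.mk_spec[k]].equilibrium(v0)
        if self.pool is not None:
            st["eca"] = np.full((batch, self.np_pool),
                                _nernst_ca(self.pool.ca_rest_mM,
                                           self.pool.ca_out_mM,
                                           self.pool.temp_c))
        else:
            st["eca"] = np.zeros((batch, 0))
        # per-instance absolute conductances (mS)
        gv = st["gvec"]
        gv_safe = gv if gv.shape[1] else np.zeros((batch, 1))
        gm = np.where(self.hh_gene[None, :] >= 0,
                      gv_safe[:, np.clip(self.hh_gene, 0, None)],
                      self.hh_gfix[None, :])
        st["g_abs"] = gm * self.areas[self.hh_comp][None, :]
        st["g_dens"] = gm
        if self.nm:
            gmm = np.where(self.mk_gene[None, :] >= 0,
                           gv_safe[:, np.clip(self.mk_gene, 0, None)],
                           self.mk_gfix[None, :])
            st["gm_abs"] = gmm * self.areas[self.mk_comp][None, :]
        else:
            st["gm_abs"] = np.zeros((batch, 0))
        st["_po"] = np.empty((batch, self.nc))
        st["_e_arr"] = np.broadcast_to(self.hh_erev[None, :],
                                       (batch, self.nc)).copy()
        if self.pool is not None and self.calc_gene >= 0:
            st["beta_ca"] = gv[:, self.calc_gene]
        elif self.pool is not None:
            st["beta_ca"] = np.full(batch, self.pool.beta_ca)
        return st

    # -- one fixed step ----------------------------------------------------

    def step(self, st: dict, tab: _Tables, istim_uA: float | np.ndarray,
             inj_comp: int, theta: float = 0.5,
             clamp: tuple[int, float] | None = None):
        """Advance the state by one step of ``tab.dt``.

        Returns the clamp current (uA, per batch element) when ``clamp``
        is given, else None.
        """
        v = st["v"]
        batch = v.shape[0]
        dt = tab.dt
        idx = ((v - V_MIN) * (1.0 / V_STEP) + 0.5).astype(np.int64)
        idx[idx < 0] = 0
        nvmax = len(self.v_grid) - 1
        idx[idx > nvmax] = nvmax

        # HH gates (exponential Euler on tables)
        if self.ng:
            ii = idx[:, self.gate_comp]
            rows = self.gate_rows[None, :]
            mi = tab.minf[rows, ii]
            ef = tab.expf[rows, ii]
            m = st["m"]
            m *= ef
            m += mi * (1.0 - ef)

        # KCa gates (direct Moczydlowski-Latorre rates, calcium dependent)
        if self.nkca:
            vk = v[:, self.kca_comp]
            cak = st["ca"][:, self.kca_pool]
            for k, (aa, av0, ak, ba, bv0, bk) in enumerate(self._kca_params):
                a = aa / (1.0 + (av0 / cak[:, k]) * np.exp(-vk[:, k] / ak))
                b = ba / (1.0 + (cak[:, k] / bv0) * np.exp(vk[:, k] / bk))
                rate = a + b
                mi = a / rate
                st["kca"][:, k] = mi + (st["kca"][:, k] - mi) * np.exp(-dt * rate)

        # Markov occupancies (expm lookup)
        if self.nm:
            im = ((v - V_MIN) * (1.0 / V_STEP_MARKOV) + 0.5).astype(np.int64)
            im[im < 0] = 0
            nvm = len(self.vm_grid) - 1
            im[im > nvm] = nvm
            iim = im[:, self.mk_comp]
            for si in range(len(self.markov_specs)):
                sel = self.mk_spec == si
                mats = tab.markov[si][iim[:, sel]]
                st["P"][:, sel, :] = np.einsum("bki,bkij->bkj",
                                               st["P"][:, sel, :], mats)

        # open fractions and conductances
        po = st["_po"]
        po[:] = 1.0
        if self.ng:
            mp = st["m"] ** self.gate_expo[None, :]
            prod = np.multiply.reduceat(mp, self.gate_group_starts, axis=1)
            po[:, self.gate_group_chan] *= prod
        if self.nkca:
            po[:, self.kca_chan] *= st["kca"]
        gpo = st["g_abs"] * po

        e_arr = st["_e_arr"]
        if len(self.ca_chan):
            e_arr[:, self.ca_chan] = st["eca"][:, self.ca_chan_pool]

        g_tot = gpo @ self.minc
        ge_tot = (gpo * e_arr) @ self.minc

        if self.nm:
            po_m = st["P"][:, :, self.mk_open].sum(axis=2)
            gpo_m = st["gm_abs"] * po_m
            g_tot += gpo_m @ self.minc_m
            ge_tot += (gpo_m * self.mk_erev[None, :]) @ self.minc_m

        # theta-method voltage solve
        cmdt = self.cm[None, :] / dt
        rhs = (cmdt - (1 - theta) * g_tot) * v \
            - (1 - theta) * (v @ self.lap.T) + ge_tot
        rhs[:, inj_comp] += istim_uA
        i_clamp = None
        if self.n == 1 and clamp is None:
            a = cmdt + theta * g_tot + self.lap[0, 0]
            vnew = rhs / a
        else:
            a = np.broadcast_to((theta * self.lap)[None, :, :],
                                (batch, self.n, self.n)).copy()
            di = np.arange(self.n)
            a[:, di, di] += cmdt + theta * g_tot
            if clamp is not None:
                ccomp, vcmd = clamp
                a[:, ccomp, :] = 0.0
                a[:, ccomp, ccomp] = 1.0
                rhs[:, ccomp] = vcmd
            vnew = np.linalg.solve(a, rhs[:, :, None])[:, :, 0]
        if clamp is not None:
            ccomp, vcmd = clamp
            ionic = g_tot[:, ccomp] * vnew[:, ccomp] - ge_tot[:, ccomp]
            axial = (vnew @ self.lap.T)[:, ccomp]
            cap = self.cm[ccomp] / dt * (vnew[:, ccomp] - v[:, ccomp])
            i_clamp = cap + ionic + axial
        st["v"] = vnew

        # calcium pools (exact exponential update with the new voltage)
        if self.np_pool:
            i_ca = np.zeros((batch, self.np_pool))
            for j, ci in enumerate(self.ca_chan):
                slot = self.ca_chan_pool[j]
                dens = st["g_dens"][:, ci] * po[:, ci] * \
                    (vnew[:, self.hh_comp[ci]] - st["eca"][:, slot]) * 1e-3
                i_ca[:, slot] += dens
            k = self.pool.influx_coeff()
            beta = st["beta_ca"][:, None]
            ca_inf = self.pool.ca_rest_mM - k * i_ca / beta
            st["ca"] = ca_inf + (st["ca"] - ca_inf) * np.exp(-beta * dt)
            st["ca"][st["ca"] < CA_FLOOR_MM] = CA_FLOOR_MM
            st["eca"] = _nernst_ca(st["ca"], self.pool.ca_out_mM,
                                   self.pool.temp_c)
        return i_clamp

    def channel_current_densities(self, st: dict) -> dict[int, np.ndarray]:
        """Per channel-instance current density (mA/cm^2) at the current
        state (single-batch diagnostics path)."""
        v = st["v"]
        po = np.ones((v.shape[0], self.nc))
        if self.ng:
            mp = st["m"] ** self.gate_expo[None, :]
            prod = np.multiply.reduceat(mp, self.gate_group_starts, axis=1)
            po[:, self.gate_group_chan] *= prod
        if self.nkca:
            po[:, self.kca_chan] *= st["kca"]
        e_arr = np.broadcast_to(self.hh_erev[None, :], po.shape).copy()
        if len(self.ca_chan):
            e_arr[:, self.ca_chan] = st["eca"][:, self.ca_chan_pool]
        out = {}
        for ci in range(self.nc):
            out[ci] = (st["g_dens"][:, ci] * po[:, ci]
                       * (v[:, self.hh_comp[ci]] - e_arr[:, ci]) * 1e-3)
        base = self.nc
        if self.nm:
            open_idx = list(self.markov_specs[0].open_states)
            po_m = st["P"][:, :, open_idx].sum(axis=2)
            gm = st["gm_abs"] / self.areas[self.mk_comp][None, :]
            for k in range(self.nm):
                out[base + k] = (gm[:, k] * po_m[:, k]
                                 * (v[:, self.mk_comp[k]] - self.mk_erev[k])
                                 * 1e-3)
        return out


def compile_model(model: CellModel) -> CompiledModel:
    """Compile (and cache on the model) the table-driven form."""
    cached = getattr(model, "_compiled", None)
    if cached is None:
        cached = CompiledModel(model)
        model._compiled = cached
    return cached


# --------------------------------------------------------------------------
# drivers
# --------------------------------------------------------------------------

def _settle(cm: CompiledModel, st: dict, settle_ms: float, theta: float,
            inj_comp: int, holding_pA: float = 0.0):
    if settle_ms <= 0:
        return
    tab = cm.tables(SETTLE_DT)
    hold = holding_pA * 1e-6
    for _ in range(int(round(settle_ms / SETTLE_DT))):
        cm.step(st, tab, hold, inj_comp, theta)


def simulate_batch(model: CellModel, gmat: np.ndarray,
                   protocol: StimulusProtocol, record: str = "soma",
                   dt: float = DEFAULT_DT,
                   settle_ms: float = DEFAULT_SETTLE_MS,
                   theta: float = 0.5,
                   stim_scale: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a whole population of conductance vectors in lock-step.

    ``gmat`` has shape (batch, n_genes).  ``stim_scale`` (length batch)
    multiplies the protocol current per batch row, so one call can sweep
    both individuals and stimulus amplitudes.  Returns
    ``(t_ms, v[batch, T])`` recorded at the ``record`` compartment on the
    uniform ``dt`` grid.
    """
    cm = compile_model(model)
    gmat = np.asarray(gmat, dtype=float)
    if gmat.ndim == 1:
        gmat = gmat[None, :]
    batch = gmat.shape[0]
    st = cm.init_state(batch, gmat)
    inj = model.comp_index(protocol.injection_site) if cm.n > 1 else 0
    rec = model.comp_index(record) if cm.n > 1 else 0
    scale = (np.ones(batch) if stim_scale is None
             else np.asarray(stim_scale, dtype=float))
    _settle(cm, st, settle_ms, theta, inj, protocol.holding_pA * scale)

    nsteps = int(round(protocol.total_ms / dt))
    t = np.arange(nsteps + 1) * dt
    istim = protocol.current_pA(t[:-1]) * 1e-6  # uA, left-edge sampling
    tab = cm.tables(dt)
    v_rec = np.empty((batch, nsteps + 1))
    v_rec[:, 0] = st["v"][:, rec]
    for k in range(nsteps):
        cm.step(st, tab, istim[k] * scale, inj, theta)
        v_rec[:, k + 1] = st["v"][:, rec]
    return t, v_rec


def simulate(model: CellModel, protocol: StimulusProtocol,
             record=("soma",), gvec: np.ndarray | None = None,
             solver: str = "fixed", dt: float = DEFAULT_DT,
             settle_ms: float = DEFAULT_SETTLE_MS, theta: float = 0.5,
             record_currents: bool = False, record_ca: bool = False,
             rtol: float = 1e-6, atol: float = 1e-6) -> VoltageTrace:
    """Integrate one model under one protocol and return traces.

    ``record`` lists compartment labels (or ``"all"``).  The model is
    initialized at steady state and settled for ``settle_ms`` at zero
    input before the protocol starts; returned time 0 is the protocol
    start.  ``solver`` is ``"fixed"`` (default, reproducible) or
    ``"adaptive"`` (LSODA with ``rtol``/``atol``).
    """
    cm = compile_model(model)
    if gvec is None:
        gvec = model.reference_vector()
    labels = model.labels() if record == "all" else list(record)
    rec_idx = [model.comp_index(l) for l in labels] if cm.n > 1 else [0]
    if cm.n == 1:
        labels = [model.compartments[0].label]
    inj = model.comp_index(protocol.injection_site) if cm.n > 1 else 0

    if solver == "adaptive":
        return _simulate_adaptive(cm, model, protocol, gvec, labels, rec_idx,
                                  inj, dt, settle_ms, rtol, atol)
    if solver != "fixed":
        raise ValueError(f"unknown solver {solver!r}")

    st = cm.init_state(1, np.asarray(gvec)[None, :])
    _settle(cm, st, settle_ms, theta, inj, protocol.holding_pA)
    nsteps = int(round(protocol.total_ms / dt))
    t = np.arange(nsteps + 1) * dt
    istim = protocol.current_pA(t[:-1]) * 1e-6
    tab = cm.tables(dt)
    v_rec = np.empty((len(rec_idx), nsteps + 1))
    v_rec[:, 0] = st["v"][0, rec_idx]
    ca_rec = (np.empty((cm.np_pool, nsteps + 1)) if record_ca and cm.np_pool
              else None)
    if ca_rec is not None:
        ca_rec[:, 0] = st["ca"][0]
    cur_rec = None
    if record_currents:
        names = _instance_names(cm)
        cur_rec = {n: np.empty(nsteps + 1) for n in names.values()}
        for ci, dens in cm.channel_current_densities(st).items():
            cur_rec[names[ci]][0] = dens[0]
    for k in range(nsteps):
        cm.step(st, tab, istim[k], inj, theta)
        v_rec[:, k + 1] = st["v"][0, rec_idx]
        if ca_rec is not None:
            ca_rec[:, k + 1] = st["ca"][0]
        if cur_rec is not None:
            for ci, dens in cm.channel_current_densities(st).items():
                cur_rec[names[ci]][k + 1] = dens[0]
    nan_check = ~np.isfinite(v_rec)
    if nan_check.any():
        kbad = int(np.argwhere(nan_check.any(axis=0))[0])
        raise FloatingPointError(
            f"solver produced a non-finite voltage at t={t[kbad]:.3f} ms")

    vd = {lab: v_rec[i] for i, lab in enumerate(labels)}
    trace = VoltageTrace(t_ms=t, v_mV=vd,
                         meta={"protocol": protocol, "solver": "fixed",
                               "dt_ms": dt})
    if ca_rec is not None:
        trace.ca_mM = {model.compartments[c].label: ca_rec[s]
                       for s, c in enumerate(cm.pool_comp)}
    if cur_rec is not None:
        site = labels[0]
        trace.currents = {site: cur_rec}
    return trace


def _instance_names(cm: CompiledModel) -> dict[int, str]:
    names = {}
    counts: dict[str, int] = {}
    for ci in range(cm.nc):
        ent = cm.model.channels[cm.hh_entry[ci]]
        lbl = cm.model.compartments[cm.hh_comp[ci]].label
        key = f"{ent.name}.{lbl}"
        names[ci] = key
    for k in range(cm.nm):
        lbl = cm.model.compartments[cm.mk_comp[k]].label
        names[cm.nc + k] = f"Na13.{lbl}"
    return names


def vclamp(model: CellModel, protocol: VClampProtocol | None = None,
           gvec: np.ndarray | None = None, dt: float = DEFAULT_DT,
           settle_ms: float = DEFAULT_SETTLE_MS,
           theta: float = 1.0) -> tuple[np.ndarray, np.ndarray, float]:
    """Somatic voltage clamp from rest.

    Settles the free model, clamps the soma at its resting potential,
    applies the command step, and returns ``(t_ms, i_pA, v_rest)``.
    Backward Euler (theta=1) is used: clamp transients are stiff and the
    damped scheme keeps the current transient monotone.
    """
    if protocol is None:
        protocol = VClampProtocol()
    cm = compile_model(model)
    if gvec is None:
        gvec = model.reference_vector()
    st = cm.init_state(1, np.asarray(gvec)[None, :])
    site = model.comp_index(protocol.site) if cm.n > 1 else 0
    _settle(cm, st, settle_ms, theta, site)
    v_rest = float(st["v"][0, site])

    nsteps = int(round(protocol.total_ms / dt))
    t = np.arange(1, nsteps + 1) * dt
    i_pa = np.empty(nsteps)
    tab = cm.tables(dt)
    for k in range(nsteps):
        tk = t[k]
        vcmd = v_rest + (protocol.step_mV
                         if protocol.onset_ms <= tk
                         < protocol.onset_ms + protocol.duration_ms else 0.0)
        ic = cm.step(st, tab, 0.0, site, theta, clamp=(site, vcmd))
        i_pa[k] = ic[0] * 1e6  # uA -> pA
    return t, i_pa, v_rest


# --------------------------------------------------------------------------
# adaptive solver (scipy LSODA) -- reference/convergence path
# --------------------------------------------------------------------------

def _simulate_adaptive(cm: CompiledModel, model: CellModel, protocol,
                       gvec, labels, rec_idx, inj, dt_out, settle_ms,
                       rtol, atol) -> VoltageTrace:
    from scipy.integrate import solve_ivp

    n = cm.n
    ng, nkca, nm, npool = cm.ng, cm.nkca, cm.nm, cm.np_pool
    nstate = n + ng + nkca + 13 * nm + npool
    gv = np.asarray(gvec, dtype=float)
    gv_safe = gv if gv.size else np.zeros(1)
    gm = np.where(cm.hh_gene >= 0, gv_safe[np.clip(cm.hh_gene, 0, None)],
                  cm.hh_gfix)
    g_abs = gm * cm.areas[cm.hh_comp]
    gmm = (np.where(cm.mk_gene >= 0, gv_safe[np.clip(cm.mk_gene, 0, None)],
                    cm.mk_gfix) * cm.areas[cm.mk_comp]) if nm else np.zeros(0)
    beta_ca = (gv[cm.calc_gene] if (cm.pool and cm.calc_gene >= 0)
               else (cm.pool.beta_ca if cm.pool else 1.0))

    def unpack(y):
        o = 0
        v = y[o:o + n]; o += n
        m = y[o:o + ng]; o += ng
        kca = y[o:o + nkca]; o += nkca
        p = y[o:o + 13 * nm].reshape(nm, 13); o += 13 * nm
        ca = y[o:o + npool]
        return v, m, kca, p, ca

    def rhs(t, y, stim_fn):
        v, m, kca, p, ca = unpack(y)
        dv = np.zeros(n)
        dm = np.zeros(ng)
        dkca = np.zeros(nkca)
        dp = np.zeros((nm, 13))
        dca = np.zeros(npool)
        eca = (_nernst_ca(np.clip(ca, CA_FLOOR_MM, None), cm.pool.ca_out_mM,
                          cm.pool.temp_c) if npool else np.zeros(0))
        po = np.ones(cm.nc)
        for k in range(ng):
            g = cm.gate_specs[cm.gate_rows[k]]
            mi, tau = gate_steady_state(g, v[cm.gate_comp[k]])
            dm[k] = (mi - m[k]) / tau
            po[cm.gate_chan[k]] *= np.clip(m[k], 0.0, 1.0) ** cm.gate_expo[k]
        for k in range(nkca):
            g = cm.kca_gates[k]
            cak = max(ca[cm.kca_pool[k]], CA_FLOOR_MM)
            mi, tau = gate_steady_state(g, v[cm.kca_comp[k]], ca=cak)
            dkca[k] = (mi - kca[k]) / tau
            po[cm.kca_chan[k]] *= np.clip(kca[k], 0.0, 1.0)
        e_arr = cm.hh_erev.copy()
        if len(cm.ca_chan):
            e_arr[cm.ca_chan] = eca[cm.ca_chan_pool]
        i_ion = np.zeros(n)
        for ci in range(cm.nc):
            i_ion[cm.hh_comp[ci]] += g_abs[ci] * po[ci] * \
                (v[cm.hh_comp[ci]] - e_arr[ci])
        for k in range(nm):
            spec = cm.markov_specs[cm.mk_spec[k]]
            q = spec.rate_matrix(float(v[cm.mk_comp[k]]))
            dp[k] = p[k] @ q
            po_m = p[k][list(spec.open_states)].sum()
            i_ion[cm.mk_comp[k]] += gmm[k] * po_m * \
                (v[cm.mk_comp[k]] - cm.mk_erev[k])
        i_ax = cm.lap @ v
        i_inj = np.zeros(n)
        i_inj[inj] = stim_fn(t) * 1e-6
        dv = (-i_ion - i_ax + i_inj) / cm.cm
        if npool:
            i_ca = np.zeros(npool)
            for j, ci in enumerate(cm.ca_chan):
                slot = cm.ca_chan_pool[j]
                i_ca[slot] += gm[ci] * po[ci] * \
                    (v[cm.hh_comp[ci]] - eca[slot]) * 1e-3
            kcoef = cm.pool.influx_coeff()
            dca = -kcoef * i_ca - beta_ca * (ca - cm.pool.ca_rest_mM)
        return np.concatenate([dv, dm, dkca, dp.ravel(), dca])

    st = cm.init_state(1, gv[None, :])
    y0 = np.concatenate([st["v"][0], st["m"][0], st["kca"][0],
                         st["P"][0].ravel(), st["ca"][0]])
    if settle_ms > 0:
        sol = solve_ivp(rhs, (0.0, settle_ms), y0, method="LSODA",
                        args=(lambda t: protocol.holding_pA,),
                        rtol=rtol, atol=atol, max_step=5.0)
        if not sol.success:
            raise FloatingPointError(f"settling failed: {sol.message}")
        y0 = sol.y[:, -1]
    t_eval = np.arange(0.0, protocol.total_ms + dt_out / 2, dt_out)

    def stim(t):
        return float(protocol.current_pA(np.array([t]))[0])

    sol = solve_ivp(rhs, (0.0, protocol.total_ms), y0, method="LSODA",
                    args=(stim,), t_eval=t_eval, rtol=rtol, atol=atol,
                    max_step=1.0)
    if not sol.success:
        raise FloatingPointError(f"adaptive solver failed: {sol.message}")
    vmat = sol.y[:n, :]
    vd = {lab: vmat[rec_idx[i]] for i, lab in enumerate(labels)}
    return VoltageTrace(t_ms=sol.t, v_mV=vd,
                        meta={"protocol": protocol, "solver": "adaptive",
                              "rtol": rtol, "atol": atol})
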