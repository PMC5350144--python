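"""Cell morphology, channel placement, and model assembly.

A :class:`CellModel` is the simulatable object: an electrotonic tree of
cylindrical (or sphere-equivalent) compartments, each carrying a set of
channel mechanisms, plus optional sub-membrane calcium pools.  Two
reference configurations ship with the package:

* ``mono``  -- a single sphere-equivalent soma (radius 9.76 um) with the
  full HH channel complement;
* ``multi`` -- 4 dendrites (15 x 0.75 um) + soma (5.8 x 5.6 um cylinder)
  + axon initial segment (2.5 x 1.5 um) + a 70 um ascending axon
  (0.3 um diameter) split into uniform segments, with sodium channels
  (13-state Markov scheme) confined to AIS and axon.

Each *channel entry* of a model config is one optimizable gene: its
maximum conductance density is shared by every compartment the entry
expands to (e.g. all axonal segments).  The calcium decay rate ("Calc")
can be declared optimizable as an extra gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .channels import (
    CalciumPool,
    GateSpec,
    MarkovChannelSpec,
    RateFn,
    resurgent_na_13state,
)
from .constants import cylinder_area_um2, sphere_area_um2
from .kinetics import KineticsSet, load_kinetics, packaged_data_path

__all__ = ["Compartment", "ChannelEntry", "ParameterRange", "CellModel",
           "build_model", "axial_conductance"]


@dataclass(frozen=True)
class Compartment:
    """One electrotonic compartment (cylinder or sphere-equivalent)."""

    label: str
    shape: str  # "cylinder" | "sphere"
    cm_uf_cm2: float = 1.0
    diam_um: float = 0.0
    length_um: float = 0.0
    radius_um: float = 0.0

    @property
    def area_um2(self) -> float:
        if self.shape == "sphere":
            return sphere_area_um2(self.radius_um)
        return cylinder_area_um2(self.diam_um, self.length_um)

    def __post_init__(self):
        if self.shape not in ("cylinder", "sphere"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.area_um2 <= 0:
            raise ValueError(f"compartment {self.label!r} has zero area")


@dataclass
class ChannelEntry:
    """One config-level channel placement (= one optimizable gene).

    ``comp_indices`` lists every compartment the entry was expanded to;
    the same density applies to all of them.
    """

    name: str
    template: str                 # compartment label in the config
    comp_indices: list[int]
    gmax: float                   # mS/cm^2 (reference/default value)
    gmax_range: tuple[float, float] | None
    erev: float | str             # mV or "ca"
    kind: str                     # "hh" | "markov13" | "leak"
    gates: tuple[GateSpec, ...] = ()
    markov_params: dict = field(default_factory=dict)

    @property
    def gene_name(self) -> str:
        return f"{self.name}.{self.template}"


@dataclass(frozen=True)
class ParameterRange:
    """Search interval of one gene (mS/cm^2, or 1/ms for Calc)."""

    name: str
    compartment: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo must be < hi")

    @property
    def mid(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass
class CaConfig:
    comp_indices: list[int]
    pool: CalciumPool
    beta_range: tuple[float, float] | None = None
    optimize_beta: bool = False


class CellModel:
    """Compartments + channel placement + passive properties."""

    def __init__(self, mode: str, compartments: list[Compartment],
                 parents: list[int], channels: list[ChannelEntry],
                 ra_ohm_cm: float, v_init: float,
                 calcium: CaConfig | None = None,
                 kinetics: KineticsSet | None = None):
        self.mode = mode
        self.compartments = compartments
        self.parents = parents  # parent index per compartment, -1 for root
        self.channels = channels
        self.ra_ohm_cm = ra_ohm_cm
        self.v_init = v_init
        self.calcium = calcium
        self.kinetics = kinetics
        self._check_tree()

    # -- structure ---------------------------------------------------------

    def _check_tree(self):
        n = len(self.compartments)
        if len(self.parents) != n:
            raise ValueError("parents length mismatch")
        roots = [i for i, p in enumerate(self.parents) if p < 0]
        if n and len(roots) != 1:
            raise ValueError("compartment tree must have exactly one root")
        # connectivity: every node reaches the root
        for i in range(n):
            seen, j = set(), i
            while self.parents[j] >= 0:
                if j in seen:
                    raise ValueError("cycle in compartment tree")
                seen.add(j)
                j = self.parents[j]

    @property
    def n_comp(self) -> int:
        return len(self.compartments)

    def comp_index(self, label: str) -> int:
        for i, c in enumerate(self.compartments):
            if c.label == label:
                return i
        raise KeyError(f"no compartment {label!r}")

    def labels(self) -> list[str]:
        return [c.label for c in self.compartments]

    def areas_cm2(self) -> np.ndarray:
        return np.array([c.area_um2 for c in self.compartments]) * 1e-8

    def axial_matrix_uS(self) -> np.ndarray:
        """Symmetric coupling-conductance matrix (uS); zero diagonal."""
        n = self.n_comp
        g = np.zeros((n, n))
        for i, p in enumerate(self.parents):
            if p >= 0:
                gij = axial_conductance(self.compartments[i],
                                        self.compartments[p], self.ra_ohm_cm)
                g[i, p] = g[p, i] = gij
        return g

    # -- genes -------------------------------------------------------------

    def parameter_ranges(self) -> list[ParameterRange]:
        """Optimizable genes in config order (conductances, then Calc)."""
        out = [ParameterRange(ch.name, ch.template, *ch.gmax_range)
               for ch in self.channels if ch.gmax_range is not None]
        if self.calcium is not None and self.calcium.optimize_beta:
            lo, hi = self.calcium.beta_range
            out.append(ParameterRange("Calc", "pool", lo, hi))
        return out

    def reference_vector(self) -> np.ndarray:
        """Default gene values (mid-range densities, config beta_ca)."""
        vals = [ch.gmax for ch in self.channels if ch.gmax_range is not None]
        if self.calcium is not None and self.calcium.optimize_beta:
            vals.append(self.calcium.pool.beta_ca)
        return np.array(vals, dtype=float)

    def gene_names(self) -> list[str]:
        return [f"{r.name}.{r.compartment}" for r in self.parameter_ranges()]


def axial_conductance(c1: Compartment, c2: Compartment,
                      ra_ohm_cm: float) -> float:
    """Coupling conductance between adjacent compartments (uS).

    Series resistance of the two half-cylinders:
    R = sum_i 4 Ra (L_i/2) / (pi d_i^2).  Symmetric in its arguments.
    A sphere-equivalent compartment is treated as a cylinder of equal
    diameter and length (diam = 2r).
    """
    r_tot = 0.0
    for c in (c1, c2):
        if c.shape == "sphere":
            d_um = length_um = 2.0 * c.radius_um
        else:
            d_um, length_um = c.diam_um, c.length_um
        if d_um <= 0:
            raise ValueError(f"compartment {c.label!r} has zero diameter")
        r_tot += (4.0 * ra_ohm_cm * (length_um * 1e-4 / 2.0)
                  / (np.pi * (d_um * 1e-4) ** 2))
    return 1e6 / r_tot  # Ohm -> uS


# --------------------------------------------------------------------------
# config parsing
# --------------------------------------------------------------------------

def _expand_compartments(cfg: dict) -> tuple[list[Compartment], list[int], dict]:
    """Expand template entries into concrete compartments and a tree."""
    n_axon = int(cfg.get("axon_segments", 15))
    comps: list[Compartment] = []
    parents: list[int] = []
    groups: dict[str, list[int]] = {}
    label_to_idx: dict[str, int] = {}

    entries = cfg["compartments"]
    # build soma/root first so attachments resolve
    deferred = []
    for entry in entries:
        label = entry["label"]
        shape = entry.get("shape", "cylinder")
        cm = float(entry.get("cm_uf_cm2", 1.0))
        count = int(entry.get("count", 1))
        attach = entry.get("attach")
        if label == "axon":
            seg_len = float(entry["length_um"]) / n_axon
            idxs = []
            for k in range(n_axon):
                comps.append(Compartment(f"axon_{k+1}", "cylinder", cm,
                                         diam_um=float(entry["diam_um"]),
                                         length_um=seg_len))
                idxs.append(len(comps) - 1)
            groups[label] = idxs
            for j, i in enumerate(idxs):
                label_to_idx[comps[i].label] = i
                deferred.append((i, attach if j == 0 else comps[idxs[j - 1]].label))
        elif count > 1:
            idxs = []
            for k in range(count):
                name = f"{label}_{k+1}"
                if shape == "sphere":
                    comps.append(Compartment(name, "sphere", cm,
                                             radius_um=float(entry["radius_um"])))
                else:
                    comps.append(Compartment(name, "cylinder", cm,
                                             diam_um=float(entry["diam_um"]),
                                             length_um=float(entry["length_um"])))
                idxs.append(len(comps) - 1)
                label_to_idx[name] = len(comps) - 1
                deferred.append((len(comps) - 1, attach))
            groups[label] = idxs
        else:
            if shape == "sphere":
                comps.append(Compartment(label, "sphere", cm,
                                         radius_um=float(entry["radius_um"])))
            else:
                comps.append(Compartment(label, "cylinder", cm,
                                         diam_um=float(entry["diam_um"]),
                                         length_um=float(entry["length_um"])))
            i = len(comps) - 1
            groups[label] = [i]
            label_to_idx[label] = i
            deferred.append((i, attach))

    parents = [-1] * len(comps)
    for i, attach in deferred:
        if attach is None:
            parents[i] = -1
        else:
            if attach not in label_to_idx and attach in groups:
                attach_idx = groups[attach][0]
            elif attach in label_to_idx:
                attach_idx = label_to_idx[attach]
            else:
                raise ValueError(f"attach target {attach!r} not defined")
            parents[i] = attach_idx
    return comps, parents, groups


def _channel_entry(spec: dict, groups: dict, kin: KineticsSet | None) -> ChannelEntry:
    name = spec["name"]
    template = spec["compartment"]
    if template not in groups:
        raise ValueError(f"channel {name!r} placed on undefined "
                         f"compartment {template!r}")
    if "gmax_range" in spec:
        lo, hi = (float(x) for x in spec["gmax_range"])
        gmax = float(spec.get("gmax", 0.5 * (lo + hi)))
        rng = (lo, hi)
    else:
        gmax = float(spec["gmax"])
        rng = None
    erev = spec["erev"]
    if not isinstance(erev, str):
        erev = float(erev)
    if name.startswith("Lkg") or name.lower().startswith("leak"):
        kind, gates, mparams = "leak", (), {}
    else:
        if kin is None or name not in kin:
            raise ValueError(f"channel {name!r} not in kinetics set")
        kind = kin.channel_type(name)
        if kind == "hh":
            gates, mparams = kin.gates(name), {}
        else:
            gates, mparams = (), kin.markov_params(name)
    return ChannelEntry(name=name, template=template,
                        comp_indices=list(groups[template]), gmax=gmax,
                        gmax_range=rng, erev=erev, kind=kind, gates=gates,
                        markov_params=mparams)


def build_model(config: str | Path | dict) -> CellModel:
    """Build a :class:`CellModel` from a YAML config (path, shipped name
    ``"mono"``/``"multi"``, or an already-parsed dict)."""
    if isinstance(config, dict):
        cfg = config
    else:
        path = Path(config)
        if not path.suffix:
            path = packaged_data_path(f"{config}.yaml")
        cfg = yaml.safe_load(path.read_text())

    kin = None
    if cfg.get("kinetics"):
        kin = load_kinetics(cfg["kinetics"])

    comps, parents, groups = _expand_compartments(cfg)
    channels = [_channel_entry(s, groups, kin)
                for s in cfg.get("channels", [])]

    calcium = None
    ca_cfg = cfg.get("calcium")
    if ca_cfg:
        idxs: list[int] = []
        for lbl in ca_cfg["compartments"]:
            idxs.extend(groups[lbl])
        pool = CalciumPool(
            ca_mM=float(ca_cfg.get("ca_rest_mM", 1e-4)),
            ca_rest_mM=float(ca_cfg.get("ca_rest_mM", 1e-4)),
            ca_out_mM=float(ca_cfg.get("ca_out_mM", 2.0)),
            beta_ca=float(ca_cfg.get("beta_ca", 1.5)),
            shell_depth_um=float(ca_cfg.get("shell_depth_um", 0.2)),
        )
        beta_range = ca_cfg.get("beta_ca_range")
        if beta_range is not None:
            beta_range = (float(beta_range[0]), float(beta_range[1]))
        calcium = CaConfig(comp_indices=idxs, pool=pool,
                           beta_range=beta_range,
                           optimize_beta=bool(ca_cfg.get("optimize_beta",
                                                         False)))

    return CellModel(mode=cfg.get("mode", "custom"), compartments=comps,
                     parents=parents, channels=channels,
                     ra_ohm_cm=float(cfg.get("ra_ohm_cm", 100.0)),
                     v_init=float(cfg.get("v_init", -65.0)),
                     calcium=calcium, kinetics=kin)
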