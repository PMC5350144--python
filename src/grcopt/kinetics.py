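"""Loading of versioned gating-kinetics sets.

The rate constants of the granule cell channel family are configuration
data, not code: a *kinetics set* is a YAML file that fully determines the
gating of every channel type (functional forms and parameters, normalized
to 30 degC).  The package ships ``grc2026a``, calibrated so that the
reference models at the mid-range conductances reproduce the canonical
granule cell phenotype (see docs/methods.md).

Schema (per channel)::

    channels:
      KV:
        type: hh
        gates:
          - name: n
            exponent: 4
            minf: {kind: sigmoid, a: 1.0, v0: -25.0, k: -9.0}
            tau:  {kind: bell, a: 3.0, v0: -40.0, k: 25.0, k2: 25.0}
            tau_min: 0.25
      Na13:
        type: markov13
        params: {alpha: 150.0, beta: 3.0, ...}

Gates may use ``alpha``/``beta`` instead of ``minf``/``tau``; the
calcium-dependent KCa gate uses ``mlkca`` rates and sets
``ca_dependent: true``.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .channels import GateSpec, RateFn
from .constants import KINETICS_TEMP_C

__all__ = ["KineticsSet", "load_kinetics", "packaged_data_path"]

_RATE_KEYS = {"kind", "a", "v0", "k", "k2", "sign"}


def packaged_data_path(name: str) -> Path:
    """Path of a data file shipped inside the package."""
    return Path(importlib.resources.files("grcopt") / "data" / name)


def _rate(d: dict) -> RateFn:
    extra = set(d) - _RATE_KEYS
    if extra:
        raise ValueError(f"unknown rate keys {sorted(extra)}")
    return RateFn(**d)


def _gate(d: dict, temp_c: float) -> GateSpec:
    kw = dict(
        name=d["name"],
        exponent=int(d.get("exponent", 1)),
        tau_min=float(d.get("tau_min", 0.0)),
        ca_dependent=bool(d.get("ca_dependent", False)),
        temp_c=temp_c,
    )
    for key in ("alpha", "beta", "minf", "tau"):
        if key in d:
            kw[key] = _rate(d[key])
    return GateSpec(**kw)


class KineticsSet:
    """A named, versioned collection of channel gating definitions."""

    def __init__(self, name: str, temp_c: float, channels: dict):
        if temp_c != KINETICS_TEMP_C:
            raise ValueError(
                f"kinetics set {name!r} is normalized to {temp_c} degC; the "
                f"simulator assumes {KINETICS_TEMP_C} degC and applies no "
                "runtime temperature scaling")
        self.name = name
        self.temp_c = temp_c
        self._channels = channels

    def channel_type(self, name: str) -> str:
        return self._channels[name]["type"]

    def gates(self, name: str) -> tuple[GateSpec, ...]:
        entry = self._channels[name]
        if entry["type"] != "hh":
            raise KeyError(f"channel {name!r} is not HH-style")
        return tuple(entry["gates"])

    def markov_params(self, name: str) -> dict:
        entry = self._channels[name]
        if entry["type"] != "markov13":
            raise KeyError(f"channel {name!r} is not a Markov scheme")
        return dict(entry.get("params", {}))

    def __contains__(self, name: str) -> bool:
        return name in self._channels

    def channel_names(self) -> list[str]:
        return list(self._channels)


def load_kinetics(source: str | Path) -> KineticsSet:
    """Load a kinetics set from a YAML file or a packaged set name.

    ``source`` may be a filesystem path or the bare name of a shipped set
    (e.g. ``"grc2026a"``).
    """
    path = Path(source)
    if not path.suffix:
        path = packaged_data_path(f"kinetics_{source}.yaml")
    raw = yaml.safe_load(path.read_text())
    temp_c = float(raw.get("temp_c", KINETICS_TEMP_C))
    channels: dict = {}
    for cname, entry in raw["channels"].items():
        ctype = entry.get("type", "hh")
        if ctype == "hh":
            gates = tuple(_gate(g, temp_c) for g in entry.get("gates", []))
            channels[cname] = {"type": "hh", "gates": gates}
        elif ctype == "markov13":
            channels[cname] = {"type": "markov13",
                               "params": entry.get("params", {})}
        else:
            raise ValueError(f"channel {cname!r}: unknown type {ctype!r}")
    return KineticsSet(raw.get("name", path.stem), temp_c, channels)
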