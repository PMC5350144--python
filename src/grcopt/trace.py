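"""Simulation output container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VoltageTrace"]


@dataclass
class VoltageTrace:
    """Time series of membrane voltage for one protocol.

    ``t_ms`` is a uniform grid starting at 0 (protocol start, after the
    settling pre-run); ``v_mV`` maps recorded compartment labels to
    voltage arrays.  Optional per-channel current densities (mA/cm^2) and
    calcium concentrations (mM) are keyed the same way.
    """

    t_ms: np.ndarray
    v_mV: dict[str, np.ndarray]
    currents: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    ca_mM: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for label, v in self.v_mV.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite voltage in {label!r}")

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.t_ms)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-9))

    def voltage(self, label: str | None = None) -> np.ndarray:
        if label is None:
            label = next(iter(self.v_mV))
        return self.v_mV[label]

    def as_dataframe(self) -> pd.DataFrame:
        cols = {"t_ms": self.t_ms}
        cols.update({f"v_{k}_mV": v for k, v in self.v_mV.items()})
        cols.update({f"ca_{k}_mM": c for k, c in self.ca_mM.items()})
        for site, chans in self.currents.items():
            cols.update({f"i_{site}_{c}_mA_cm2": a for c, a in chans.items()})
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.as_dataframe().to_csv(path, index=False)
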