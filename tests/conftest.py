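import numpy as np
import pytest

from grcopt.morphology import build_model


@pytest.fixture(scope="session")
def mono_model():
    """Reference mono-compartment model (mid-range conductances)."""
    return build_model("mono")


@pytest.fixture(scope="session")
def multi_model():
    """Reference multi-compartment model."""
    return build_model("multi")


def passive_mono(g_leak=0.0568, e_leak=-65.0):
    """Single sphere with a leak only (analytic RC reference)."""
    return build_model({
        "mode": "mono",
        "compartments": [{"label": "soma", "shape": "sphere",
                          "radius_um": 9.76}],
        "channels": [{"name": "Lkg1", "compartment": "soma",
                      "gmax": g_leak, "erev": e_leak}],
        "v_init": e_leak,
    })


def passive_multi():
    """Multi-compartment morphology with leak only, common reversal."""
    import yaml
    from grcopt.kinetics import packaged_data_path
    cfg = yaml.safe_load(packaged_data_path("multi.yaml").read_text())
    cfg["kinetics"] = None
    cfg["calcium"] = None
    cfg["channels"] = [c for c in cfg["channels"] if c["name"] == "Lkg"]
    for c in cfg["channels"]:
        c["erev"] = -65.0
        del c["gmax_range"]
        c["gmax"] = 0.02
    cfg["v_init"] = -65.0
    return build_model(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
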