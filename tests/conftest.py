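import numpy as np
import pytest

from g4conform import build_mock_quadruplex, preset


@pytest.fixture(scope="session")
def z_axis():
    return np.array([0.0, 0.0, 1.0])


@pytest.fixture(scope="session")
def conventional_build():
    """Low-noise conventional V-loop fixture ensemble + ground truth."""
    return build_mock_quadruplex(preset("vloop_conventional", sigma=0.05, n_models=4))


@pytest.fixture(scope="session")
def alternative_build():
    return build_mock_quadruplex(preset("vloop_alternative", sigma=0.05, n_models=4))


@pytest.fixture(scope="session")
def parallel_model():
    """Single noise-free parallel-topology model."""
    ens, truth = build_mock_quadruplex(preset("parallel", sigma=0.0, n_models=1))
    return ens.models[0], truth


def truth_summary(truth):
    """Ground-truth labels in the same shape as QuartetTopology.summary()."""
    out = {
        "layers": [sorted(map(tuple, layer)) for layer in truth["layers"]],
        "columns": {tuple(map(tuple, col)) for col in truth["columns"]},
        "tracts": sorted((tuple(map(tuple, k)), o) for k, o in truth["tracts"]),
        "loops": [
            (l["kind"], tuple(l["anchor5"]), tuple(l["anchor3"]))
            for l in truth["loops"]
        ],
        "polarities": list(truth["polarities"]),
        "relative_polarities": list(truth["relative_polarities"]),
    }
    if truth["vloop"]:
        v = truth["vloop"]
        out["vloops"] = [
            (tuple(v["anchor5"]), tuple(v["anchor3"]), v["subtype"], v["polarity_class"])
        ]
    else:
        out["vloops"] = []
    return out


def detected_summary(topology):
    s = topology.summary()
    return {
        "layers": [sorted(layer) for layer in s["layers"]],
        "columns": {tuple(col) for col in s["columns"]},
        "tracts": sorted(s["tracts"]),
        "loops": s["loops"],
        "polarities": s["polarities"],
        "relative_polarities": s["relative_polarities"],
        "vloops": s["vloops"],
    }
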