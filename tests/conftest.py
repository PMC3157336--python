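import numpy as np
import pytest

from mirtfnet import (
    MIRNA,
    TF,
    ExpressionProfile,
    RegulatorCatalog,
    RunConfig,
)


@pytest.fixture
def toy_catalog() -> RegulatorCatalog:
    """The 5-node cascade toy: root M targets a kinase and a TF.

    M -> {K1, TFA}; K1-TFB interaction; TFA targets TFC; TFD is isolated.
    """
    cat = RegulatorCatalog()
    cat.add("MIR-M", MIRNA, {"K1", "TFA", "G1", "G2"}, "toy")
    cat.add("TFA", TF, {"TFC", "G3", "G4"}, "toy")
    cat.add("TFB", TF, {"G5", "G6"}, "toy")
    cat.add("TFC", TF, {"G7", "G8"}, "toy")
    cat.add("TFD", TF, {"G9", "G10"}, "toy")
    cat.kinase_tf_edges.add(("K1", "TFB"))
    return cat


@pytest.fixture
def small_profile() -> ExpressionProfile:
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(1, 101)]
    return ExpressionProfile(
        experiment_id="exp1",
        transfecting_mirna="MIR-M",
        values={g: float(v) for g, v in zip(genes, rng.normal(0, 1, 100))},
    )


@pytest.fixture
def loose_config() -> RunConfig:
    return RunConfig(min_targets=2)
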