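import numpy as np
import pytest

from gamcp.combo import DesignSpec
from gamcp.graph import GraphSpec, closure_weights
from gamcp.numerics import CorrBlock, CorrelationModel


@pytest.fixture(scope="session")
def two_dose_graph() -> GraphSpec:
    """Two doses vs control, primary/secondary endpoints: H1/H2 primary
    (high/low dose), H3/H4 secondary.  Alpha is split over the primaries;
    a rejected primary passes half its weight down to its own secondary and
    half across to the other primary."""
    return GraphSpec(
        ("H1", "H2", "H3", "H4"),
        np.array([0.5, 0.5, 0.0, 0.0]),
        np.array([[0.0, 0.5, 0.5, 0.0],
                  [0.5, 0.0, 0.0, 0.5],
                  [0.0, 1.0, 0.0, 0.0],
                  [1.0, 0.0, 0.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def two_dose_corr() -> CorrelationModel:
    """Within each endpoint the two dose-vs-control z statistics share the
    control arm (correlation 0.5 under balanced randomization); the
    correlation across endpoints is unknown."""
    return CorrelationModel((CorrBlock.equicorrelated(("H1", "H2"), 0.5),
                             CorrBlock.equicorrelated(("H3", "H4"), 0.5)))


@pytest.fixture(scope="session")
def two_dose_design(two_dose_graph, two_dose_corr) -> DesignSpec:
    return DesignSpec(two_dose_graph, two_dose_corr, alpha=0.025, t_planned=0.5)


@pytest.fixture(scope="session")
def two_dose_weights(two_dose_graph):
    return closure_weights(two_dose_graph)


@pytest.fixture(scope="session")
def stage1_p() -> dict:
    return {"H1": 0.00045, "H2": 0.0952, "H3": 0.0225, "H4": 0.1104}


@pytest.fixture(scope="session")
def stage2_p() -> dict:
    return {"H2": 0.1121, "H3": 0.0112, "H4": 0.1153}


def random_graph(rng: np.random.Generator, k: int, exhaustive: bool = True
                 ) -> GraphSpec:
    """Random valid graph; exhaustive graphs have all row/weight sums one."""
    w = rng.dirichlet(np.ones(k))
    g = np.zeros((k, k))
    for i in range(k):
        row = rng.dirichlet(np.ones(k - 1))
        if not exhaustive:
            row = row * rng.uniform(0.3, 1.0)
        g[i, [j for j in range(k) if j != i]] = row
    if not exhaustive:
        w = w * rng.uniform(0.3, 1.0)
    labels = tuple(f"H{i+1}" for i in range(k))
    return GraphSpec(labels, w, g)
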