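import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point

from soilsource.datamodel import BackgroundTable, FeatureLayer, SampleTable
from soilsource.simulate import SimulationConfig, simulate


@pytest.fixture
def background():
    df = pd.DataFrame(
        {
            "background": [12.80, 0.14, 150.0, 25.0, 27.8, 30.0, 84.2, 1300.0, 4000.0],
            "screening": [40.0, 0.30, 150.0, 50.0, 60.0, 70.0, 200.0, np.nan, np.nan],
            "source_label": ["national"] * 9,
        },
        index=pd.Index(["As", "Cd", "Cr", "Cu", "Ni", "Pb", "Zn", "Ca", "Mg"],
                       name="element"),
    )
    return BackgroundTable(df)


def make_samples(conc: dict, x=None, y=None, altitude=None) -> SampleTable:
    """Build a SampleTable from a dict of element -> concentration arrays."""
    n = len(next(iter(conc.values())))
    data = pd.DataFrame(
        {
            "x": x if x is not None else np.linspace(0.0, 1000.0, n),
            "y": y if y is not None else np.zeros(n),
            "altitude": altitude if altitude is not None else np.full(n, 100.0),
            **{k: np.asarray(v, float) for k, v in conc.items()},
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="site_id"),
    )
    return SampleTable(data, list(conc))


@pytest.fixture
def simple_layers():
    return {
        "chemical_factory": FeatureLayer("chemical_factory", [Point(3.0, 4.0)]),
        "river": FeatureLayer("river", [LineString([(0, 0), (10, 0)])]),
    }


@pytest.fixture(scope="session")
def study():
    """One deterministic synthetic study at the default conditions."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_study():
    return simulate(SimulationConfig(seed=0, noise_cv=0.0))


def true_pathway_map(config: SimulationConfig, elements) -> dict:
    return {
        (e, fac): list(p)
        for e in elements
        for fac, p in config.pathways.items()
    }
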