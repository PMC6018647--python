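import numpy as np
import pandas as pd
import pytest

from traitdisp.io_validation import (
    AnalysisBundle,
    BinaryTraitMatrix,
    ContinuousTraitMatrix,
    EnvironmentTable,
    OccurrenceMatrix,
)


def make_occurrence(rows: dict[str, list[str]], species: list[str]) -> OccurrenceMatrix:
    """Build an occurrence matrix from plot -> species-present lists."""
    data = pd.DataFrame(0, index=list(rows), columns=species)
    for plot, present in rows.items():
        data.loc[plot, present] = 1
    return OccurrenceMatrix(data)


def make_distance(ids: list[str], pairs: dict[tuple[str, str], float], metric="euclidean"):
    from traitdisp.dissimilarity import DistanceMatrix

    n = len(ids)
    m = np.zeros((n, n))
    for (a, b), d in pairs.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(ids, m, metric)


@pytest.fixture
def toy_bundle() -> AnalysisBundle:
    """Hand-built 4-plot / 6-species bundle, fully deterministic."""
    species = [f"s{i}" for i in range(1, 7)]
    occ = make_occurrence(
        {
            "p1": ["s1", "s2", "s3"],
            "p2": ["s2", "s4", "s5"],
            "p3": ["s1", "s5", "s6"],
            "p4": ["s3", "s4", "s6"],
        },
        species,
    )
    rng = np.random.default_rng(42)
    sm = pd.DataFrame(
        rng.integers(0, 2, size=(6, 10)), index=species,
        columns=[f"m{k}" for k in range(10)],
    )
    sm.iloc[:, 0] = 1  # no all-zero rows, column shared by all
    rut = pd.DataFrame(
        rng.normal(size=(6, 4)) + np.arange(4), index=species,
        columns=[f"t{k}" for k in range(4)],
    )
    soil = pd.DataFrame(
        {
            "P": [4.0, 9.0, 6.0, 12.0],
            "Ca": [100.0, 300.0, 150.0, 380.0],
            "sand": [70.0, 30.0, 60.0, 25.0],
        },
        index=occ.plot_ids,
    )
    coords = pd.DataFrame(
        {
            "longitude": [-73.5, -73.48, -73.0, -72.6],
            "latitude": [-4.2, -4.21, -4.0, -3.8],
        },
        index=occ.plot_ids,
    )
    return AnalysisBundle(
        occ,
        BinaryTraitMatrix(sm),
        ContinuousTraitMatrix(rut),
        EnvironmentTable(soil, coords),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
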