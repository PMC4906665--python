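import numpy as np
import pytest

from tempoweb import (
    InteractionMatrix,
    SpeciesRecord,
    TemporalNetworkSeries,
    TraitTable,
    paper_like,
    simulate_series,
)


def make_matrix(weights, period="P00", plants=None, birds=None):
    w = np.asarray(weights, dtype=float)
    plants = plants or [f"p{i}" for i in range(w.shape[0])]
    birds = birds or [f"b{j}" for j in range(w.shape[1])]
    return InteractionMatrix(period_label=period, plants=plants, birds=birds, weights=w)


def random_matrix(rng, n_rows=None, n_cols=None, fill=0.5, quantitative=True, max_side=8):
    """Random valid interaction matrix (no empty rows/columns)."""
    n_rows = n_rows or int(rng.integers(2, max_side + 1))
    n_cols = n_cols or int(rng.integers(2, max_side + 1))
    for _ in range(1000):
        B = (rng.random((n_rows, n_cols)) < fill).astype(float)
        if B.sum(axis=1).min() > 0 and B.sum(axis=0).min() > 0:
            break
    else:
        B = np.ones((n_rows, n_cols))
    if quantitative:
        B *= rng.integers(1, 20, B.shape)
    return make_matrix(B)


def small_traits(n_plants=4, n_res=2, n_mig=2):
    recs = [
        SpeciesRecord(f"p{i}", f"plant {i}", "plant", "not_applicable", seeds_per_fruit=5.0)
        for i in range(n_plants)
    ]
    recs += [SpeciesRecord(f"b{j}", f"res {j}", "bird", "resident") for j in range(n_res)]
    recs += [
        SpeciesRecord(f"b{j + n_res}", f"mig {j}", "bird", "migratory") for j in range(n_mig)
    ]
    return TraitTable(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20231114)


@pytest.fixture(scope="session")
def paper_series():
    """One paper_like synthetic dataset shared by the slower tests."""
    series, fai, truth = simulate_series(paper_like(seed=0))
    return series, fai, truth
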