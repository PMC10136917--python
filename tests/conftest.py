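import numpy as np
import pandas as pd
import pytest

from tinnet.instruments import GAD7, PHQ9, ItemResponseMatrix
from tinnet.network import SymptomNetwork
from tinnet.stability import BootConfig
from tinnet.synth import GeneratorSpec, sample_cohort


def toy_matrix(values, communities=None, items=None):
    """Build a small ItemResponseMatrix from a plain array."""
    values = np.asarray(values)
    n, p = values.shape
    if items is None:
        items = [f"X{j+1}" for j in range(p)]
    if communities is None:
        half = max(2, p // 2)
        communities = {
            it: ("left" if j < half else "right") for j, it in enumerate(items)
        }
    return ItemResponseMatrix(
        subjects=[f"s{i}" for i in range(n)],
        items=list(items),
        communities=communities,
        values=values,
    )


def toy_network(labels, edges, communities=None):
    """SymptomNetwork from an edge dict {(a, b): weight}."""
    p = len(labels)
    W = np.zeros((p, p))
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), w in edges.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return SymptomNetwork(
        labels=list(labels), communities=dict(communities or {}), W=W
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-shaped synthetic cohort: 566 subjects, 9+7 ordinal items."""
    return sample_cohort(GeneratorSpec(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for resampling tests."""
    return sample_cohort(GeneratorSpec(n_subjects=250, seed=3))


@pytest.fixture(scope="session")
def fast_boot():
    """Reduced resampling settings keeping bootstrap tests quick."""
    return BootConfig(
        nboots=25, seed=11, n_lambdas=25,
        drop_proportions=(0.05, 0.3),
    )


@pytest.fixture(scope="session")
def raw_table(default_cohort):
    df = default_cohort.responses.to_frame().reset_index(names="subject")
    return df


@pytest.fixture()
def instruments():
    return (PHQ9, GAD7)
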