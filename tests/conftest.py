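import numpy as np
import pandas as pd
import pytest

from hdselect import ProfileDataset, SyntheticSpec, binarize, generate, generate_levels


@pytest.fixture(scope="session")
def small_registry():
    """A modest registry for unit tests: d=64, L=8, range [0, 100]."""
    return generate_levels(64, 8, v_min=0.0, v_max=100.0, seed=42)


@pytest.fixture
def toy_dataset():
    """Six samples, four features, two classes: tiny but trainable."""
    abundance = pd.DataFrame(
        [
            [1, 0, 1, 0],
            [1, 1, 1, 0],
            [1, 0, 0, 0],
            [0, 1, 0, 1],
            [0, 1, 1, 1],
            [0, 0, 0, 1],
        ],
        index=[f"s{i}" for i in range(6)],
        columns=["fA", "fB", "fC", "fD"],
        dtype=float,
    )
    labels = pd.Series(["case"] * 3 + ["control"] * 3, index=abundance.index)
    return ProfileDataset(abundance=abundance, labels=labels)


@pytest.fixture
def planted_binary():
    """Factory: binarised synthetic cohort with planted species for a seed."""

    def make(seed=0, **overrides):
        spec = SyntheticSpec(seed=seed, **overrides)
        ds, informative = generate(spec)
        return binarize(ds), informative

    return make


def make_study_table(species, samples, values, unclassified):
    """Taxa x samples table in MetaPhlAn orientation with an unclassified row."""
    table = pd.DataFrame(values, index=species, columns=samples, dtype=float)
    table.loc["unclassified"] = unclassified
    return table.reindex(["unclassified"] + list(species))
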