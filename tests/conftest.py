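import numpy as np
import pandas as pd
import pytest

from patchselect import (
    EggCountDataset,
    SelectionParams,
    SimulationConfig,
    simulate_experiment,
    standard_designs,
)


@pytest.fixture(scope="session")
def designs():
    return standard_designs()


@pytest.fixture(scope="session")
def neutral_data():
    """One simulated experiment at the no-preference point (fixed seed)."""
    return simulate_experiment(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def preference_data():
    """One simulated experiment at a strong apple preference (fixed seed)."""
    return simulate_experiment(
        SimulationConfig(true_params=SelectionParams(0.9, 0.8), seed=202)
    )


def dataset_from_counts(designs, counts, strain="test"):
    """Build a dataset from {treatment: {replicate_id: {substrate_id: eggs}}}.

    Substrates missing from a replicate's mapping get zero eggs, so every
    replicate covers its design's full substrate set.
    """
    rows = []
    for treatment, reps in counts.items():
        design = designs[treatment]
        for rep, cells in reps.items():
            for s in design.substrates:
                rows.append(
                    (
                        rep,
                        strain,
                        treatment,
                        s.patch_id,
                        s.substrate_id,
                        s.resource,
                        int(cells.get(s.substrate_id, 0)),
                    )
                )
    frame = pd.DataFrame(
        rows,
        columns=[
            "replicate_id",
            "strain",
            "treatment",
            "patch_id",
            "substrate_id",
            "resource",
            "eggs",
        ],
    )
    return EggCountDataset(frame)


@pytest.fixture()
def make_dataset(designs):
    def _make(counts, strain="test"):
        return dataset_from_counts(designs, counts, strain=strain)

    return _make
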