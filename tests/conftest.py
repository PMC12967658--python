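import numpy as np
import pytest
from hypothesis import settings

import graphstab as gs

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def property_table():
    return gs.load_property_table()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default study conditions: 60-residue helix WT, 100 active / 300
    inactive double mutants, 5% label noise, seed 0."""
    return gs.make_synthetic_dataset(gs.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def synthetic_graphs(synthetic_dataset):
    graphs, labels, conservation, table = gs.prepare_graphs(
        synthetic_dataset.wt, synthetic_dataset.structure, synthetic_dataset.records
    )
    return graphs, labels, conservation, table


@pytest.fixture(scope="session")
def recovery_cv_reports():
    """The parameter-recovery experiment: three full pipelines (dataset
    generation -> featurization -> stratified 5-fold CV with default model
    config), seeds 0..2.  Shared session-wide because it is the expensive
    training experiment several tests interrogate."""
    reports = {}
    for seed in (0, 1, 2):
        ds = gs.make_synthetic_dataset(gs.SyntheticConfig(seed=seed))
        graphs, labels, _, _ = gs.prepare_graphs(ds.wt, ds.structure, ds.records)
        reports[seed] = gs.cross_validate(
            graphs, labels, k=5, seed=seed, collect_models=True
        )
    return reports


@pytest.fixture()
def tiny_pdb(tmp_path):
    """Three-residue toy PDB (ALA, GLY, LEU with Cα records only)."""
    text = (
        "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  CA  LEU A   3       7.600   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "toy.pdb"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def quick_model(synthetic_graphs):
    """A cheaply trained model for plumbing tests that only need *a* trained
    network, not an accurate one."""
    graphs, labels, conservation, table = synthetic_graphs
    est = gs.GraphStabilityClassifier(
        hidden_units=16, max_epochs=8, patience=8, batch_size=32, seed=0
    )
    est.fit(graphs[:120], labels[:120])
    return est.model_
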