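"""Shared fixtures: a small synthetic study reused across test modules.

Session-scoped so the connectome and cohorts are generated once; tests
must not mutate them.
"""

import numpy as np
import pytest

import circuitmap as cm


@pytest.fixture(scope="session")
def spec():
    return cm.SyntheticSpec(
        n_subjects=6,
        n_timepoints=80,
        n_patients=60,
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def circuit(spec):
    return cm.make_circuit(spec)


@pytest.fixture(scope="session")
def connectome(spec):
    return cm.make_connectome(spec)


@pytest.fixture(scope="session")
def lesion_cohort(spec, circuit, connectome):
    return cm.make_cohort(spec.replace(modality="lesion", rng_seed=321),
                          circuit, connectome, name="lesion-a")


@pytest.fixture(scope="session")
def tms_cohort(spec, circuit, connectome):
    return cm.make_cohort(spec.replace(modality="tms_scalp", rng_seed=322),
                          circuit, connectome, name="tms-a")


@pytest.fixture(scope="session")
def dbs_cohort(spec, circuit, connectome):
    return cm.make_cohort(spec.replace(modality="dbs", rng_seed=323),
                          circuit, connectome, name="dbs-a")


@pytest.fixture()
def grid8():
    return cm.make_grid((8, 8, 8), voxel_size_mm=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
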