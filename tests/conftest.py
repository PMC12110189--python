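import numpy as np
import pytest

from timeprox import (AnalysisConfig, SimulationParams, generate_cohort,
                      reference_clinical_table, write_cohort)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def reference_clinical_path(tmp_path_factory):
    """CSV of the synthetic 27-patient reference-cohort transcription."""
    path = tmp_path_factory.mktemp("clin") / "clinical.csv"
    reference_clinical_table().to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient cohort with slides, shared across tests (read-only)."""
    return generate_cohort(SimulationParams(n_patients=6, seed=11))


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory, small_cohort):
    d = tmp_path_factory.mktemp("cohort6")
    write_cohort(small_cohort, d)
    return d


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
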