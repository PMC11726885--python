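import pytest

from coroflow.pipeline import StudyConfig, case_specs, run_case, run_case_matrix


@pytest.fixture(scope="session")
def study_cfg() -> StudyConfig:
    """Default study configuration (paper_twin geometry, 12 cycles at 2 ms)."""
    return StudyConfig()


@pytest.fixture(scope="session")
def matrix_results(study_cfg):
    """The full six-case study matrix, simulated once per session."""
    return run_case_matrix(study_cfg)


@pytest.fixture(scope="session")
def healthy_case(matrix_results):
    return matrix_results["healthy"]


@pytest.fixture(scope="session")
def patient_case(matrix_results):
    return matrix_results["patient"]


@pytest.fixture(scope="session")
def healthy_spec():
    return case_specs(["healthy"])[0]
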