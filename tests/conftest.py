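import hypothesis
import pytest

from nerveblock.pipeline import recover_duration as estimate_arm_duration  # noqa: F401
from nerveblock.simulate import CohortSpec, generate_study

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, deadline=None, max_examples=60
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study_seed1(tmp_path_factory):
    """Default four-arm synthetic study (seed 1) written to CSV files."""
    tables = generate_study(cohort_spec=CohortSpec(seed=1))
    d = tmp_path_factory.mktemp("study_seed1")
    cohort = d / "cohort.csv"
    measurements = d / "measurements.csv"
    tables.cohort.to_csv(cohort, index=False)
    tables.measurements.to_csv(measurements, index=False)
    return {"tables": tables, "cohort_csv": cohort, "measurements_csv": measurements}
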