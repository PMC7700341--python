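import hypothesis
import pytest

from kidscreen import simulate

hypothesis.settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic cohort shared across tests."""
    return simulate.generate(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def codebook(bundle):
    return bundle.codebook


@pytest.fixture(scope="session")
def complete_bundle():
    """Cohort without any missingness (standardization sets coincide)."""
    cfg = simulate.SimConfig(
        seed=2,
        retention=1.0,
        missing_anthro=0.0,
        blood_given=1.0,
        missing_biomarker=0.0,
        missing_biomarker_shared=0.0,
        missing_item=0.0,
    )
    return simulate.generate(cfg)
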