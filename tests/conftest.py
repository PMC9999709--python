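import pytest
from hypothesis import settings

from irapen_cea import paper_base_case

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_very_high():
    return paper_base_case("very_high", diabetic=False)


@pytest.fixture(scope="session")
def base_low_no_diabetes():
    return paper_base_case("low", diabetic=False)


@pytest.fixture(scope="session")
def all_base_cases():
    return {(label, diabetic): paper_base_case(label, diabetic)
            for diabetic in (False, True)
            for label in ("low", "moderate", "high", "very_high")}
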