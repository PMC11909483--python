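import pytest

from wbcbt import estimation
from wbcbt import synthetic_trial as st


@pytest.fixture(scope="session")
def small_trial():
    """A small default-condition trial shared across read-only tests."""
    return st.generate_trial(st.GeneratorConfig(n=420, seed=42))


@pytest.fixture(scope="session")
def small_frame(small_trial):
    return estimation.build_analysis_frame(
        small_trial.baseline, small_trial.arms, small_trial.followup
    )


@pytest.fixture(scope="session")
def complete_trial():
    """Same conditions but with no dropout (everyone completes)."""
    return st.generate_trial(
        st.GeneratorConfig(n=420, seed=42, dropout=st.DropoutModel.none())
    )


@pytest.fixture(scope="session")
def complete_frame(complete_trial):
    return estimation.build_analysis_frame(
        complete_trial.baseline, complete_trial.arms, complete_trial.followup
    )
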