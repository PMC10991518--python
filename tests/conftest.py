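import pytest


@pytest.fixture(scope="session")
def desk_run():
    """The desk-scale reference experiment: synthetic structured corpus,
    normalizer/projector fit, and a full (short) training run.  Trained once
    per session and shared by the recovery tests."""
    from contiglm.experiment import run_desk_experiment
    return run_desk_experiment(seed=1)
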