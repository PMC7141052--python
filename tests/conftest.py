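import pytest
from hypothesis import HealthCheck, settings

from gazeparse.synthetic_data import GrammarConfig, gen_treebank
from gazeparse.transition_model import train, training_events

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_treebank():
    """Small deterministic case-marked SOV treebank."""
    return gen_treebank(GrammarConfig(n_sentences=60), seed=11)


@pytest.fixture(scope="session")
def trained_model(toy_treebank):
    """MaxEnt transition model trained on the toy treebank's oracle events."""
    events, skipped = training_events(toy_treebank)
    assert skipped == 0
    return train(events, seed=0)
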