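import pytest

from camannotate.simulate import StudyConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across tests: 6 participants,
    4 h of capture at the 24 s device rate."""
    cfg = StudyConfig(n_participants=6, day_length_s=4 * 3600.0,
                      capture_rate_centres=(24.0,), seed=11)
    annotations, truth = generate_study(cfg)
    return cfg, annotations, truth
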