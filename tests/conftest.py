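import numpy as np
import pytest

from avec import ArtifactSpec, BeatSeries, SyntheticConfig, generate_clean, generate_labeled


@pytest.fixture
def rng():
    return np.random.default_rng(20140546)


@pytest.fixture(scope="session")
def clean_rsa():
    """Default-parameter artifact-free canine RSA series (bpm)."""
    return generate_clean(SyntheticConfig(n_beats=800, seed=42))


@pytest.fixture(scope="session")
def spiky_rsa():
    """RSA series with 1 % labeled transmission spikes."""
    return generate_labeled(
        SyntheticConfig(
            n_beats=800,
            artifacts=(ArtifactSpec("spike", 0.01, 60.0),),
            seed=42,
        )
    )


@pytest.fixture
def constant_series():
    return BeatSeries(values=np.full(100, 100.0), unit="bpm")
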