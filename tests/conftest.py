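import numpy as np
import pytest

from callrhythm import SynthConfig, events_from_records, generate_corpus


@pytest.fixture
def tiny_events():
    """One call: pulses at 0/2/4 s, one pant at 1 s."""
    return events_from_records(
        [
            ("f1", "c1", "pulse", 0.0, 0.4),
            ("f1", "c1", "pant", 1.0, 0.3),
            ("f1", "c1", "pulse", 2.0, 0.4),
            ("f1", "c1", "pulse", 4.0, 0.4),
        ]
    )


@pytest.fixture(scope="session")
def clean_corpus():
    """Zero-jitter, every cycle panted at the exact midpoint."""
    cfg = SynthConfig(
        n_calls=6,
        pulses_per_call=12,
        jitter_cv=0.0,
        pant_insertion_prob=1.0,
        pant_phase=0.5,
        pant_phase_sd=0.0,
        seed=7,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def noisy_corpus():
    """Moderate jitter, pants in ~half the cycles."""
    cfg = SynthConfig(n_calls=20, jitter_cv=0.05, pant_insertion_prob=0.5, seed=1)
    return generate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
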