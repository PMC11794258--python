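import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from twotk.core import ActType, Address, SpeechAct
from twotk.datasets import load_monte_cristo
from twotk.synthetic_data import GeneratorConfig, generate_dialogue


@pytest.fixture(scope="session")
def monte_cristo():
    return load_monte_cristo()


@pytest.fixture
def make_acts():
    """Factory for quick hand-built act sequences.

    ``spec`` is a list of (delta_task, decisive) pairs; addresses are laid
    out sequentially in one theme.
    """

    def _make(spec, speaker="A"):
        acts = []
        for i, (d_task, dec) in enumerate(spec, start=1):
            acts.append(
                SpeechAct(
                    speaker=speaker,
                    epsilon=i,
                    content=f"utt-{i}",
                    act_type=ActType.MK,
                    address=Address(1, i),
                    polarity={"task": d_task, "interlocutor": 0},
                    decisivity=dec,
                )
            )
        return acts

    return _make


@pytest.fixture
def random_dialogue():
    """Factory for a validated synthetic dialogue at a given seed."""

    def _make(seed=0, **overrides):
        rng = np.random.default_rng(seed)
        kwargs = dict(
            n_concatenations=int(rng.integers(1, 6)),
            acts_per_concatenation=(1, 8),
            p_delta_task=float(rng.uniform(0, 1)),
            p_delta_interlocutor=float(rng.uniform(0, 1)),
            p_decisive_given_positive=float(rng.uniform(0, 1)),
            turn_persistence=float(rng.uniform(0, 1)),
            seed=seed,
        )
        kwargs.update(overrides)
        return generate_dialogue(GeneratorConfig(**kwargs))

    return _make
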