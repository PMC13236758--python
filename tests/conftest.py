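import numpy as np
import pytest

from sopsim import NodeSpec, canonical_config


@pytest.fixture
def canonical_object() -> NodeSpec:
    return NodeSpec("obj", "object", p1=0.75, pd1=0.1, pd2=0.02)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def config_for(schedule, **overrides):
    """Canonical ModelConfig matching a schedule's node roles."""
    objects = [n for n, r in schedule.roles.items() if r == "object"]
    contexts = [n for n, r in schedule.roles.items() if r == "context"]
    return canonical_config(objects, contexts, **overrides)


@pytest.fixture
def make_config():
    return config_for
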