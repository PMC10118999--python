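from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def dna_text(min_size: int = 1, max_size: int = 60, alphabet: str = "ACGT"):
    """Hypothesis strategy for DNA strings."""
    return st.text(alphabet=sorted(alphabet), min_size=min_size, max_size=max_size)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20230411)


def random_dna(rnd: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rnd.choice(alphabet) for _ in range(n))
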