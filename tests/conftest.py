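import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper

from ribodesign.engine import EngineConfig


@pytest.fixture(scope="session")
def toy_config() -> EngineConfig:
    return EngineConfig(parameter_set="toy")


@pytest.fixture(scope="session")
def turner_config() -> EngineConfig:
    return EngineConfig(parameter_set="turner1999")


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20140910)


def random_structure(rng: random.Random, n: int) -> str:
    """A random valid structure by recursive pair-or-skip construction."""
    chars = ["."] * n

    def rec(lo: int, hi: int) -> None:  # 1-based inclusive
        if hi - lo < 4:
            return
        if rng.random() < 0.5:
            rec(lo + 1, hi)
            return
        k = rng.randrange(lo + 4, hi + 1)
        chars[lo - 1], chars[k - 1] = "(", ")"
        rec(lo + 1, k - 1)
        rec(k + 1, hi)

    rec(1, n)
    return "".join(chars)
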