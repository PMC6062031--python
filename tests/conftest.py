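import random

import pytest

from splitmatch.synthetic import ALPHABETS

ALPHABET_SIZES = {2: "AB", 4: "ACGT", 20: ALPHABETS["protein"], 64: ALPHABETS["alpha64"]}


def random_cases(alphabet: str, n_cases: int, seed: int,
                 m_max: int = 12, n_max: int = 300):
    """Seeded random (pattern, text) pairs with 1 <= m <= min(n, m_max),
    m <= n <= n_max.  Patterns are drawn from the text half the time so
    that matches actually occur."""
    rng = random.Random(seed)
    cases = []
    for _ in range(n_cases):
        n = rng.randint(1, n_max)
        text = "".join(rng.choice(alphabet) for _ in range(n))
        m = rng.randint(1, min(m_max, n))
        if rng.random() < 0.5:
            s = rng.randint(0, n - m)
            pattern = text[s : s + m]
        else:
            pattern = "".join(rng.choice(alphabet) for _ in range(m))
        cases.append((pattern, text))
    return cases


@pytest.fixture(scope="session")
def small_random_cases():
    """A modest per-alphabet case set shared by unit-level property tests."""
    return {size: random_cases(a, 60, seed=size) for size, a in ALPHABET_SIZES.items()}
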