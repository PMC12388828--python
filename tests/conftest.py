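import numpy as np
import pytest

from rnaensemble.structure_io import ContactMap, RnaSequence


def random_sequence(rng: np.random.Generator, n: int, id: str = "seq") -> RnaSequence:
    return RnaSequence(id, "".join(rng.choice(list("ACGU"), size=n)))


def random_contact_map(
    rng: np.random.Generator, n: int, max_pairs: int | None = None
) -> ContactMap:
    """Random matching over positions (crossing pairs allowed)."""
    if max_pairs is None:
        max_pairs = n // 3
    order = rng.permutation(n)
    pairs = set()
    k = 0
    for a, b in zip(order[::2], order[1::2]):
        i, j = (int(a), int(b)) if a < b else (int(b), int(a))
        if j - i >= 4:
            pairs.add((i, j))
            k += 1
        if k >= max_pairs:
            break
    return ContactMap(n=n, pairs=frozenset(pairs))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_benchmark():
    """30 synthetic structures with 4 simulated learners (session-cached)."""
    from rnaensemble.learner_stack import SyntheticStructureConfig, simulate_benchmark

    cfg = SyntheticStructureConfig(n_range=(40, 70))
    return simulate_benchmark(30, cfg=cfg, seed=42)
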