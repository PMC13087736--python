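import numpy as np
import pytest

import subrate as sr


@pytest.fixture(scope="session")
def tandem_source() -> str:
    """Simple-repeat regime: ~545 nt unit, 4.2 diverged copies."""
    return sr.generate(
        sr.RepeatSpec(
            kind="tandem",
            total_length=2290,
            unit_length=545,
            copy_number=4.2,
            divergence=0.02,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def hor_source_small() -> str:
    """Alpha-satellite-like regime at a test-friendly 6 kb."""
    return sr.generate(
        sr.RepeatSpec(
            kind="hor",
            total_length=6000,
            unit_length=171,
            monomers_per_unit=6,
            divergence=0.02,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def random_source() -> str:
    return sr.random_sequence(3000, 7)


def random_histogram(rng: np.random.Generator, *, singleton_only: bool = False):
    """A small random abundance histogram with a_1 >= 1."""
    k = int(rng.integers(4, 31))
    a = {1: int(rng.integers(1, 200))}
    if not singleton_only:
        for i in rng.choice(np.arange(2, 12), size=rng.integers(0, 4), replace=False):
            a[int(i)] = int(rng.integers(1, 30))
    return sr.AbundanceHistogram.from_counts(k, a)
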