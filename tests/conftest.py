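import pytest

from shinglefp import generate_permutations


@pytest.fixture(scope="session")
def params128():
    """Small hash family for fast tests."""
    return generate_permutations(128, seed=42)


@pytest.fixture(scope="session")
def params2048():
    """Default-size hash family (MHFP6 dimensionality)."""
    return generate_permutations(2048, seed=42)
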