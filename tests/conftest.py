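import pytest

from gaitshield.paillier import generate_keypair, keypair_from_primes


@pytest.fixture(scope="session")
def toy_keypair():
    """The exhaustively checkable modulus n = 35 (p=5, q=7)."""
    return keypair_from_primes(5, 7)


@pytest.fixture(scope="session")
def keypair_128():
    """A reproducible 128-bit modulus keypair for encrypted-projection tests."""
    return generate_keypair(64, crypto_seed=20240101)
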