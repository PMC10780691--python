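"""Paillier cryptosystem with signed fixed-point encoding.

The scheme is additively homomorphic over Z_n: products of ciphertexts
decrypt to sums of plaintexts, and raising a ciphertext to an integer
power decrypts to a plaintext-scalar product.  Those two primitives are
exactly what an encrypted-domain linear projection needs, which is why
this module exposes nothing beyond them.

Key generation follows the product-form private key

    lambda = (p - 1) (q - 1),        mu = lambda^{-1} mod n,

with g fixed to n + 1, which gives the simplified decryption identity
``m = L(c^lambda mod n^2) * mu mod n`` where ``L(x) = (x - 1) / n``.

Real-valued gait features are carried through the integer plaintext
space with a decimal fixed-point encoding: ``value ~ mantissa / 10^s``
with residues above n/2 interpreted as negative (half-range signed
convention).
"""

from __future__ import annotations

import hashlib
import random
import secrets
from dataclasses import dataclass, field
from math import gcd

__all__ = [
    "PaillierPublicKey",
    "PaillierPrivateKey",
    "EncodedInteger",
    "Ciphertext",
    "KeyGenerationError",
    "EncodingOverflowError",
    "InvalidRandomizerError",
    "KeyMismatchError",
    "ScaleMismatchError",
    "generate_keypair",
    "keypair_from_primes",
    "encode_real",
    "decode_real",
    "signed_value",
    "encrypt",
    "decrypt",
    "add_encrypted",
    "scalar_multiply",
]

DEFAULT_SCALE_EXP = 6

# number of Miller-Rabin witnesses; error probability <= 4^-40
_MR_ROUNDS = 40
_MAX_PRIME_ATTEMPTS = 10_000


class KeyGenerationError(RuntimeError):
    """Prime search exhausted its attempt budget."""


class EncodingOverflowError(OverflowError):
    """Fixed-point mantissa would leave the signed half-range (-n/2, n/2)."""


class InvalidRandomizerError(ValueError):
    """Encryption randomizer r is not a unit of Z_n."""


class KeyMismatchError(ValueError):
    """Operation mixes material from different keypairs."""


class ScaleMismatchError(ValueError):
    """Homomorphic addition of operands with different fixed-point scales."""


@dataclass(frozen=True)
class PaillierPublicKey:
    n: int
    g: int
    prime_bits: int
    key_id: str = ""
    n_sq: int = field(init=False, repr=False, default=0)

    def __post_init__(self) -> None:
        if self.g != self.n + 1:
            raise ValueError("generator must be n + 1")
        if self.n % 2 == 0:
            raise ValueError("modulus must be odd")
        object.__setattr__(self, "n_sq", self.n * self.n)
        if not self.key_id:
            object.__setattr__(self, "key_id", _key_id(self.n))


@dataclass(frozen=True)
class PaillierPrivateKey:
    lam: int
    mu: int
    n: int
    key_id: str = ""

    def __post_init__(self) -> None:
        if (self.lam * self.mu) % self.n != 1:
            raise ValueError("mu is not the modular inverse of lambda mod n")
        if not self.key_id:
            object.__setattr__(self, "key_id", _key_id(self.n))


@dataclass(frozen=True)
class EncodedInteger:
    """Signed fixed-point plaintext: value = signed(mantissa) / 10^scale_exp."""

    mantissa: int
    scale_exp: int


@dataclass(frozen=True)
class Ciphertext:
    value: int
    scale_exp: int
    key_id: str


def _key_id(n: int) -> str:
    return hashlib.sha256(hex(n).encode()).hexdigest()[:12]


def _is_probable_prime(n: int, rng: random.Random, rounds: int = _MR_ROUNDS) -> bool:
    if n < 2:
        return False
    for p in (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37):
        if n % p == 0:
            return n == p
    d, s = n - 1, 0
    while d % 2 == 0:
        d //= 2
        s += 1
    for _ in range(rounds):
        a = rng.randrange(2, n - 1)
        x = pow(a, d, n)
        if x in (1, n - 1):
            continue
        for _ in range(s - 1):
            x = x * x % n
            if x == n - 1:
                break
        else:
            return False
    return True


def _random_prime(bits: int, rng: random.Random) -> int:
    for _ in range(_MAX_PRIME_ATTEMPTS):
        # force top bit (exact bit length) and bottom bit (odd)
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | 1
        if _is_probable_prime(cand, rng):
            return cand
    raise KeyGenerationError(f"no {bits}-bit prime found in {_MAX_PRIME_ATTEMPTS} attempts")


def generate_keypair(
    prime_bits: int, crypto_seed: int | None = None
) -> tuple[PaillierPublicKey, PaillierPrivateKey]:
    """Generate a keypair from two independent primes of ``prime_bits`` bits.

    Primes are regenerated until ``bit_length(n) == 2 * prime_bits``, so the
    modulus length is a deterministic function of the argument.  ``crypto_seed``
    exists for reproducible tests; production keys use the OS entropy source.
    """
    if prime_bits < 8:
        raise ValueError("prime_bits must be >= 8")
    rng = random.Random(crypto_seed) if crypto_seed is not None else secrets.SystemRandom()
    for _ in range(_MAX_PRIME_ATTEMPTS):
        p = _random_prime(prime_bits, rng)
        q = _random_prime(prime_bits, rng)
        if p == q:
            continue
        n = p * q
        if n.bit_length() == 2 * prime_bits:
            return keypair_from_primes(p, q, prime_bits=prime_bits)
    raise KeyGenerationError("could not reach the target modulus length")


def keypair_from_primes(
    p: int, q: int, prime_bits: int | None = None
) -> tuple[PaillierPublicKey, PaillierPrivateKey]:
    """Build a keypair from explicitly supplied primes (tests, toy moduli)."""
    if p == q:
        raise ValueError("primes must be distinct")
    n = p * q
    lam = (p - 1) * (q - 1)
    mu = pow(lam, -1, n)
    bits = prime_bits if prime_bits is not None else max(p.bit_length(), q.bit_length())
    key_id = _key_id(n)
    pub = PaillierPublicKey(n=n, g=n + 1, prime_bits=bits, key_id=key_id)
    priv = PaillierPrivateKey(lam=lam, mu=mu, n=n, key_id=key_id)
    return pub, priv


def encode_real(value: float, scale_exp: int, n: int) -> EncodedInteger:
    """Encode a real as a signed decimal fixed-point residue mod n."""
    if scale_exp < 0:
        raise ValueError("scale_exp must be non-negative")
    mantissa = round(value * 10**scale_exp)
    if 2 * abs(mantissa) >= n:
        raise EncodingOverflowError(
            f"|{value}| at scale 1e{scale_exp} exceeds the signed half-range of n={n}"
        )
    return EncodedInteger(mantissa=mantissa % n, scale_exp=scale_exp)


def signed_value(mantissa: int, n: int) -> int:
    """Map a residue of Z_n to the signed half-range (-n/2, n/2)."""
    return mantissa - n if 2 * mantissa > n else mantissa


def decode_real(m: EncodedInteger, n: int) -> float:
    return signed_value(m.mantissa, n) / 10**m.scale_exp


def encrypt(
    pub: PaillierPublicKey,
    m: EncodedInteger,
    r: int | None = None,
    rng: random.Random | None = None,
) -> Ciphertext:
    """Encrypt an encoded plaintext: c = g^m * r^n mod n^2.

    ``r`` may be pinned for deterministic tests; otherwise it is drawn
    uniformly from the units of Z_n (``rng`` selects the reproducibility
    channel, defaulting to OS entropy).
    """
    n, n_sq = pub.n, pub.n_sq
    if r is None:
        draw = rng if rng is not None else secrets.SystemRandom()
        while True:
            r = draw.randrange(1, n)
            if gcd(r, n) == 1:
                break
    elif not (0 < r < n) or gcd(r, n) != 1:
        raise InvalidRandomizerError(f"r={r} is not a unit modulo n")
    # g = n + 1 gives g^m = 1 + m*n (mod n^2)
    c = (1 + m.mantissa * n) % n_sq * pow(r, n, n_sq) % n_sq
    return Ciphertext(value=c, scale_exp=m.scale_exp, key_id=pub.key_id)


def decrypt(priv: PaillierPrivateKey, c: Ciphertext) -> EncodedInteger:
    """Recover the encoded plaintext: m = L(c^lambda mod n^2) * mu mod n."""
    if c.key_id != priv.key_id:
        raise KeyMismatchError("ciphertext was produced under a different key")
    n = priv.n
    x = pow(c.value, priv.lam, n * n)
    mantissa = (x - 1) // n * priv.mu % n
    return EncodedInteger(mantissa=mantissa, scale_exp=c.scale_exp)


def add_encrypted(c1: Ciphertext, c2: Ciphertext, pub: PaillierPublicKey) -> Ciphertext:
    """Homomorphic addition: the ciphertext product decrypts to m1 + m2 mod n."""
    if c1.key_id != c2.key_id or c1.key_id != pub.key_id:
        raise KeyMismatchError("operands were encrypted under different keys")
    if c1.scale_exp != c2.scale_exp:
        raise ScaleMismatchError(
            f"cannot add fixed-point scales 1e{c1.scale_exp} and 1e{c2.scale_exp}"
        )
    return Ciphertext(
        value=c1.value * c2.value % pub.n_sq,
        scale_exp=c1.scale_exp,
        key_id=c1.key_id,
    )


def scalar_multiply(c: Ciphertext, k: EncodedInteger, pub: PaillierPublicKey) -> Ciphertext:
    """Homomorphic plaintext scalar: c^k decrypts to m * k mod n.

    The result's fixed-point scale is the sum of the operand scales; the
    caller is responsible for the signed half-range via the overflow guard
    (see :func:`gaitshield.projection.overflow_bound_ok`).
    """
    if c.key_id != pub.key_id:
        raise KeyMismatchError("ciphertext was produced under a different key")
    return Ciphertext(
        value=pow(c.value, k.mantissa, pub.n_sq),
        scale_exp=c.scale_exp + k.scale_exp,
        key_id=c.key_id,
    )
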