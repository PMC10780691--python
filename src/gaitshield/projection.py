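"""Seeded Gaussian random projection as a cancelable biometric transform.

A length-j feature vector is multiplied by a j x q Gaussian matrix with
q < j.  The map is many-to-one, so the protected template cannot be
inverted (the linear system an attacker would have to solve is
underdetermined), and it is revocable: a new seed issues a fresh matrix
and hence a fresh template from the same biometric.

The same projection runs in two domains:

* plaintext (:func:`project_plain`) — ordinary matrix-vector product;
* ciphertext (:func:`project_encrypted`) — the matrix is quantized to
  integer mantissas and each output component is accumulated as a chain
  of Paillier scalar-multiplications and additions, i.e.
  ``prod_i  c_i ^ M_ik  mod n^2``.

After client-side decryption the two routes agree exactly at the
integer mantissa level, for any keypair — which is what lets protected
templates from different hospitals (different keys) be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.linalg import null_space

from .paillier import (
    Ciphertext,
    KeyMismatchError,
    PaillierPrivateKey,
    PaillierPublicKey,
    ScaleMismatchError,
    signed_value,
)

__all__ = [
    "ProjectionMatrix",
    "QuantizedProjectionMatrix",
    "TransformedVector",
    "NoninvertibilityReport",
    "RenewalNoopError",
    "OverflowGuardError",
    "generate_matrix",
    "project_plain",
    "quantize_matrix",
    "dequantize_matrix",
    "overflow_bound_ok",
    "project_encrypted",
    "decrypt_transformed",
    "verify_noninvertibility",
    "renew",
]


class RenewalNoopError(ValueError):
    """Renewal requested with the seed already in use."""


class OverflowGuardError(ArithmeticError):
    """Encrypted projection refused: accumulated product could wrap mod n."""


@dataclass(frozen=True)
class ProjectionMatrix:
    """j x q Gaussian matrix with i.i.d. N(0, 1/q) entries, reproducible from seed."""

    entries: np.ndarray
    j: int
    q: int
    seed: int

    def __post_init__(self) -> None:
        if self.entries.shape != (self.j, self.q):
            raise ValueError("entries shape does not match (j, q)")


@dataclass(frozen=True)
class QuantizedProjectionMatrix:
    """Integer-mantissa twin of a ProjectionMatrix at decimal scale 10^-scale_exp."""

    mantissas: np.ndarray  # int64, j x q
    scale_exp: int
    j: int
    q: int
    seed: int


@dataclass(frozen=True)
class TransformedVector:
    values: np.ndarray
    seed: int
    scale_provenance: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NoninvertibilityReport:
    rank: int
    n_unknowns: int
    underdetermined: bool
    consistent: bool
    witness_preimages: tuple[np.ndarray, np.ndarray] | None


def generate_matrix(j: int, q: int, seed: int) -> ProjectionMatrix:
    """Draw a j x q matrix of i.i.d. N(0, 1/q) entries from a PCG64 stream.

    The generator family is pinned (numpy default_rng / PCG64) so a seed
    reproduces the same matrix across platforms — the seed, not the
    entries, is what gets persisted and what renewability rotates.
    """
    if j < 1 or q < 1:
        raise ValueError("matrix dimensions must be positive")
    rng = np.random.default_rng(seed)
    entries = rng.normal(0.0, 1.0 / np.sqrt(q), size=(j, q))
    return ProjectionMatrix(entries=entries, j=j, q=q, seed=seed)


def project_plain(x: np.ndarray, M: ProjectionMatrix) -> TransformedVector:
    """y_k = sum_i x_i M_ik — the unprotected reference projection."""
    x = np.asarray(x, dtype=float)
    if x.shape != (M.j,):
        raise ValueError(f"expected a length-{M.j} vector, got shape {x.shape}")
    return TransformedVector(values=x @ M.entries, seed=M.seed)


def quantize_matrix(M: ProjectionMatrix, scale_exp: int) -> QuantizedProjectionMatrix:
    if scale_exp < 0:
        raise ValueError("scale_exp must be non-negative")
    mantissas = np.rint(M.entries * 10**scale_exp).astype(np.int64)
    return QuantizedProjectionMatrix(
        mantissas=mantissas, scale_exp=scale_exp, j=M.j, q=M.q, seed=M.seed
    )


def dequantize_matrix(Mq: QuantizedProjectionMatrix) -> np.ndarray:
    return Mq.mantissas.astype(float) / 10**Mq.scale_exp


def overflow_bound_ok(
    pub: PaillierPublicKey,
    j: int,
    feat_scale: int,
    mat_scale: int,
    max_abs_feature: float,
    max_abs_entry: float,
) -> bool:
    """Check the worst-case encrypted inner product stays in (-n/2, n/2).

    Uses exact rational arithmetic and a strict margin (the worst case must
    stay strictly inside the representable half-range) so no rounding of the
    bound itself can approve a wrapping computation.
    """
    worst = (
        j
        * Fraction(max_abs_feature)
        * 10**feat_scale
        * Fraction(max_abs_entry)
        * 10**mat_scale
    )
    return 2 * worst < pub.n - 1


def project_encrypted(
    enc_x: list[Ciphertext],
    Mq: QuantizedProjectionMatrix,
    pub: PaillierPublicKey,
    max_abs_feature: float = 1000.0,
) -> list[Ciphertext]:
    """Random projection in the ciphertext domain.

    Component k is ``prod_i enc_x[i] ** Mq.mantissas[i, k]  (mod n^2)`` —
    each factor a homomorphic plaintext-scalar product, the running product
    a homomorphic sum.  Signed matrix mantissas enter as residues mod n.

    The server cannot see the plaintext features, so ``max_abs_feature`` is
    a contractual bound on their magnitude that the client vouches for; the
    overflow guard combines it with the quantized entries actually present.
    """
    if len(enc_x) != Mq.j:
        raise ValueError(f"expected {Mq.j} ciphertexts, got {len(enc_x)}")
    key_ids = {c.key_id for c in enc_x}
    if key_ids != {pub.key_id}:
        raise KeyMismatchError("ciphertext vector mixes keys or does not match pub")
    scales = {c.scale_exp for c in enc_x}
    if len(scales) != 1:
        raise ScaleMismatchError("ciphertext vector mixes fixed-point scales")
    feat_scale = scales.pop()
    max_abs_entry = float(np.abs(Mq.mantissas).max()) / 10**Mq.scale_exp
    if not overflow_bound_ok(
        pub, Mq.j, feat_scale, Mq.scale_exp, max_abs_feature, max_abs_entry
    ):
        raise OverflowGuardError("projection could exceed the signed half-range")
    n, n_sq = pub.n, pub.n_sq
    out_scale = feat_scale + Mq.scale_exp
    result: list[Ciphertext] = []
    for k in range(Mq.q):
        acc = 1  # encryption of 0 with unit randomizer
        for i in range(Mq.j):
            e = int(Mq.mantissas[i, k]) % n
            acc = acc * pow(enc_x[i].value, e, n_sq) % n_sq
        result.append(Ciphertext(value=acc, scale_exp=out_scale, key_id=pub.key_id))
    return result


def decrypt_transformed(
    priv: PaillierPrivateKey,
    enc_y: list[Ciphertext],
    total_scale: int | None = None,
) -> TransformedVector:
    """Client-side decryption of the projected template.

    Each component is decrypted, mapped through the signed half-range
    convention, and rescaled by the accumulated fixed-point scale (feature
    scale + matrix scale, read from the ciphertexts unless overridden).
    """
    from .paillier import decrypt  # local import to keep module deps one-way

    if not enc_y:
        return TransformedVector(values=np.empty(0), seed=-1, scale_provenance=0)
    scale = total_scale if total_scale is not None else enc_y[0].scale_exp
    mantissas = [signed_value(decrypt(priv, c).mantissa, priv.n) for c in enc_y]
    values = np.array(mantissas, dtype=float) / 10**scale
    return TransformedVector(values=values, seed=-1, scale_provenance=scale)


def decrypt_transformed_mantissas(
    priv: PaillierPrivateKey, enc_y: list[Ciphertext]
) -> list[int]:
    """Signed integer mantissas of the projected template (exact, no rescale)."""
    from .paillier import decrypt

    return [signed_value(decrypt(priv, c).mantissa, priv.n) for c in enc_y]


def verify_noninvertibility(
    M: ProjectionMatrix,
    y: TransformedVector,
    tol: float = 1e-9,
) -> NoninvertibilityReport:
    """Rank argument for noninvertibility of the protected template.

    An attacker holding the matrix and the protected vector y must solve
    ``M^T x = y`` for the original template x.  With q < j the coefficient
    matrix has rank at most q < j unknowns, so by the Rouche-Capelli
    theorem the consistent system has an affine space of solutions; the
    report carries two distinct preimages (one least-squares solution and
    its translate along a null-space direction) as an explicit witness.
    """
    A = M.entries.T  # q x j coefficient matrix
    rank = int(np.linalg.matrix_rank(A))
    x_hat, *_ = np.linalg.lstsq(A, y.values, rcond=None)
    consistent = bool(np.linalg.norm(A @ x_hat - y.values) <= max(tol, 1e-8))
    underdetermined = rank < M.j
    witnesses = None
    if consistent and underdetermined:
        ns = null_space(A)
        v = ns[:, 0]
        x_prime = x_hat + v
        if (
            np.linalg.norm(A @ x_prime - y.values) <= max(tol, 1e-8)
            and np.linalg.norm(v) > 0
        ):
            witnesses = (x_hat, x_prime)
    return NoninvertibilityReport(
        rank=rank,
        n_unknowns=M.j,
        underdetermined=underdetermined,
        consistent=consistent,
        witness_preimages=witnesses,
    )


def renew(old: ProjectionMatrix, new_seed: int) -> ProjectionMatrix:
    """Issue a fresh projection matrix (revoking the old template) by seed rotation."""
    if new_seed == old.seed:
        raise RenewalNoopError("renewal requires a seed different from the current one")
    return generate_matrix(old.j, old.q, new_seed)
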