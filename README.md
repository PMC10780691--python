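# gaitshield

Privacy-preserving gait biometrics for neurodegenerative-disease
screening.

Gait abnormalities are early symptoms of several neurodegenerative
diseases, and video-based gait analysis feeds machine-learning
screening systems — but gait is a biometric: once leaked it cannot be
reissued, and it exposes private attributes of the patient.
`gaitshield` implements a **hybrid template-protection scheme** for
gait feature vectors, together with the full measurement pipeline
around it, so that the accuracy cost of protection and its security
properties can be evaluated end to end on synthetic cohorts:

1. **Paillier partially homomorphic encryption.** With public key
   (n, g), n = pq, g = n + 1, a feature f encrypts as
   c ≡ g^f · r^n (mod n²). Products of ciphertexts decrypt to sums of
   plaintexts, and c^k decrypts to k·f — exactly the operations a
   linear projection needs. The private key is (λ, μ) with
   λ = (p−1)(q−1) and μ ≡ λ⁻¹ (mod n); decryption is
   f = L(c^λ mod n²)·μ mod n with L(x) = (x−1)/n.
2. **Cancelable biometrics by Gaussian random projection.** A seeded
   j×q matrix M with i.i.d. N(0, 1/q) entries (q < j) maps the
   template x to y = xᵀM. The map is many-to-one — recovering x from
   (M, y) means solving an underdetermined linear system, which by the
   Rouché–Capelli theorem has infinitely many solutions
   (*noninvertibility*) — and rotating the seed issues a fresh,
   unlinkable template from the same biometric (*renewability*), per
   ISO/IEC 24745.
3. **The hybrid:** the client encrypts its features; the provider
   server performs the projection *in the ciphertext domain*
   (y_cp[k] = ∏ᵢ cᵢ^{M̃ᵢₖ} mod n² with integer-quantized matrix
   entries); the client decrypts only the projected template, which is
   then safe to store centrally and to classify on an ML server. The
   decrypted result is key-independent, so protected templates from
   different hospitals are comparable without key sharing.

Around the scheme the package provides: feature extraction from 14
2D pose keypoints (subject tracking, constant-velocity Kalman
smoothing, peak removal + linear interpolation, spatiotemporal
kinematics, five joint angles, sigma-lognormal stroke decomposition of
the speed profile), a synthetic two-class walking-cohort generator, an
LSTM-with-attention classifier (score(h_t, h_s) = h_tᵀ·W·h_s) with a
subject-disjoint cross-validation harness, and a role-separated CLI.

## Worked example

Protect one feature vector end to end:

```python
import numpy as np
from gaitshield import (
    generate_keypair, encode_real, encrypt,
    generate_matrix, quantize_matrix, project_encrypted,
    decrypt_transformed, project_plain, verify_noninvertibility,
)

pub, priv = generate_keypair(prime_bits=64)      # 128-bit modulus
x = np.array([4.2, -1.7, 0.3, 2.9, -0.8])        # a length-5 template
M = generate_matrix(j=5, q=4, seed=42)           # cancelable transform
Mq = quantize_matrix(M, scale_exp=6)

enc = [encrypt(pub, encode_real(v, 6, pub.n)) for v in x]
enc_y = project_encrypted(enc, Mq, pub)          # server side, ciphertext only
y = decrypt_transformed(priv, enc_y)             # client side

print(np.round(y.values, 6))
print(np.round(project_plain(x, M).values, 6))   # plaintext reference
print(verify_noninvertibility(M, y).underdetermined)
```

prints

```
[2.244012 0.812984 1.925704 1.134656]
[2.24401  0.812982 1.925701 1.134657]
True
```

— the encrypted-domain projection agrees with the plaintext one to the
fixed-point resolution (exactly, at the integer mantissa level), and
the protected template is certifiably noninvertible (rank 4 < 5
unknowns, with an explicit second preimage in the report).

The full protected-vs-unprotected ablation on a synthetic cohort:

```python
from gaitshield import generate_cohort, run_ablation, CVPlan, ModelConfig

cohort = generate_cohort(n_healthy=10, n_patient=10,
                         recordings_per_subject=3, n_frames=120, seed=11)
res = run_ablation(cohort, ModelConfig(), CVPlan(n_folds=5, seed=11))
print(res.unprotected.accuracy, res.protected.accuracy, res.delta["accuracy"])
```

On this cohort the unprotected arm reaches ~96.7% mean accuracy and the
protected arm ~97.8%, i.e. a Δ of about +1.1 points — protection at
q = j−1 costs essentially nothing, consistent with the
information-preserving character of a near-square Gaussian projection.

The same workflow is available as a role-separated CLI
(`gaitshield run-all --workdir out/ --seed 7`), which chains
synth → extract → keygen → encrypt → project → decrypt → train with a
role log asserting that the projection server never touches plaintext
features or the private key.

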