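# Methods

This note documents the models, the numerical choices, and the open
design decisions behind `gaitshield`, in the order data flows through
the package.

## Paillier layer

**Key generation.** Two independent random primes of `prime_bits` bits
each (Miller–Rabin, 40 witness rounds, error probability ≤ 4⁻⁴⁰; top
bit of every candidate forced). Primes are regenerated until
`bit_length(n) = 2·prime_bits`, so the modulus length is a
deterministic function of the security parameter. The private key uses
the product form λ = (p−1)(q−1) with μ = λ⁻¹ mod n — a valid variant
of the scheme (the classical presentation uses lcm(p−1, q−1)); the
product form is self-consistent with the decryption identity used
here, but keys are not interchangeable with third-party Paillier
implementations that use the lcm convention. g is fixed to n+1, which
makes g^m = 1 + mn (mod n²) and keeps encryption cheap.

**Two randomness channels.** Primes and encryption randomizers r come
from the OS entropy source by default and from a seedable generator
only when a `crypto_seed` is passed (tests, reproducible pipelines).
Everything else (matrices, cohorts, training) flows through seeded
numpy PCG64 generators.

**Fixed-point encoding.** Real features are carried as
`mantissa = round(value·10^s) mod n` with residues above n/2 decoding
as negative (half-range signed convention). Default s = 6 for both
features and matrix entries: at a 128-bit modulus the worst-case
encrypted inner product j·|x|ₘₐₓ·10⁶·|M|ₘₐₓ·10⁶ for j ≈ 30 and
pixel-scale features sits around 10¹⁷–10¹⁸, comfortably below
n/2 ≈ 1.7·10³⁸. The overflow guard checks this bound in exact rational
arithmetic and rejects at strictly below (n−1)/2, a one-integer safety
margin over the representable half-range so that no rounding of the
bound itself can approve a wrapping computation.

## Random projection layer

Matrices are j×q with i.i.d. N(0, 1/q) entries drawn from
`numpy.random.default_rng(seed)` (PCG64) — the generator family is
pinned because the seed *is* the persisted secret; entries are never
stored. Default q = j−1. For the encrypted route the matrix is
quantized to integer mantissas at scale 10⁻⁶ (per-entry error ≤
5·10⁻⁷), and each output component is the ciphertext product
∏ᵢ cᵢ^{M̃ᵢₖ} mod n². The decrypted mantissas equal the big-integer
matrix–vector product of the quantized inputs exactly, which yields
two stronger-than-float invariants: bit-exact agreement between the
encrypted and plaintext routes, and bit-exact key-independence of the
protected template across keypairs.

Noninvertibility is verified constructively: the report carries
rank(Mᵀ), the number of unknowns j, and — when the system is
consistent and underdetermined — two distinct preimages (a
least-squares solution and its translate along a null-space
direction), both reproducing y to 1e−9. Renewability is seed rotation;
renewal with the seed already in use is an error rather than a silent
no-op.

Sequences are protected per time step with the same matrix across
frames and subjects; applying the projection instead to the pooled
30-slot summary vector is supported (that is what the file-based CLI
flow protects) but the ablation uses the per-frame route so the
classifier still sees a sequence.

## Feature pipeline

Order: track → Kalman smooth → peak removal/interpolation → features.

**Tracking** selects, per frame, the candidate skeleton minimizing the
summed Euclidean distance over jointly observed keypoints to the
previous selection; frames with no candidates are marked missing and
the tracker coasts.

**Kalman smoothing** is a per-keypoint, per-axis constant-velocity
model (state: position, velocity) with a white-acceleration process of
spectral density 2·10⁵ px²/s⁴ and measurement noise 25 px², run as a
forward filter plus Rauch–Tung–Striebel backward pass. The smoother
(rather than a causal filter) matters: gait keypoints oscillate at
~1–2 Hz with tens of pixels of amplitude, and a lagging causal
estimate distorts exactly the kinematics being measured. The process
variance was chosen so the smoother tracks those oscillations with
sub-pixel bias while still roughly halving 5-px measurement noise;
both variances are configurable. Measurements whose innovation exceeds
8 predicted standard deviations are treated as missing (spike
gating), and missing measurements are predict-only steps.

**Peak removal/interpolation** re-flags frames whose per-step
displacement exceeds `spike_factor` (default 5) times the keypoint's
median step, then linearly interpolates every missing interior value
between nearest valid neighbours (edges take the nearest valid value).
An all-missing channel is an explicit error. Pose confidences below
0.1 count as missing from the start.

**Kinematics** (per inter-frame step, on the neck trajectory by
default): Δx, Δy, d = √(Δx²+Δy²), v = d/Δt and component velocities,
acceleration channels, and the tangent angle ρ. Two deliberate
conventions: ρ uses the quadrant-aware atan2(Δy, Δx) so the return leg
of a walk (direction reversal) is not aliased onto the outbound one;
and the default acceleration is the ratio form a = v/Δt, with the
conventional difference form (central differences of v) available via
`accel_mode="difference"`. The ratio form is dimensionally a shortcut;
it is kept as the default deliberately and documented here.

**Corner angles** are interior angles at the middle joint
(arccos of the normalized dot product, in [0, π]): nose–neck–hip
midpoint, neck–hip midpoint–knee, shoulder–elbow–wrist,
hip–knee–ankle, and right knee–hip midpoint–left knee. The
single-sided angles use the right limb by default; left-side variants
are a configuration away. Degenerate zero-length limbs yield NaN,
which downstream summaries skip.

**Sigma-lognormal decomposition** models the speed profile as a sum of
lognormal strokes v(t) = D/(σ√(2π)(t−t₀))·exp(−(ln(t−t₀)−μ)²/2σ²).
Extraction is greedy: take the largest remaining peak above 5% of the
original maximum, fit one stroke by bounded trust-region least squares
(four σ₀ initializations ∈ {0.1, 0.2, 0.3, 0.5}; t₀ anchored just
before the peak's 10%-height support; D₀ from the peak-height
identity), subtract, repeat until residual energy < 2% of the original
or 8 strokes. Stroke direction angles θ_start/θ_end are the trajectory
tangent angle interpolated at the stroke's 1st/99th percentile times
t₀ + exp(μ + σ·Φ⁻¹(p)). On noiseless profiles recovery is essentially
exact (≪ 5% per parameter); overlapping strokes trade amplitude
between components, which is inherent to the greedy scheme.

**Summary template.** The 30-slot layout packs mean and standard
deviation of seven kinematic channels (d, v, vx, vy, a, ay, ρ) and the
five corner angles, plus six stroke globals (count, mean D, μ, σ,
θ_start, θ_end). The composition of a length-30 gait vector is not
canonical; this layout is this package's documented choice and is
fully configurable by name.

## Synthetic cohorts

The generator emulates a sagittal-view hospital walking video after
pose estimation: hips translate at the walking speed with vertical bob
at twice the stride frequency; thigh, shank and arm angles are
phase-locked sinusoids with per-stride duration jitter
(stride_time_cv); 14 keypoints follow by forward kinematics at
100 px/m with 1 px additive noise. Class profiles: healthy
1.2 m/s, 0.95 Hz, CV 3%, arm swing 0.35 rad; dementia-like 0.75 m/s,
0.80 Hz, CV 9%, arm swing 0.15 rad, larger trunk bob. These encode the
qualitative gait abnormalities that motivate screening (slower, more
variable, reduced arm swing) with magnitudes chosen to be plausible,
not as claims about real effect sizes. Subjects get ±8% speed (and
similar) between-subject jitter; 2–3 recordings each, alternating
direction; corruption injects 3% missing keypoints and 1% coordinate
spikes (≥ 20× the median step) by default.

What passing tests on this generator do show: the cleaning stages
recover the uncorrupted track to ≤ 2 px; the full protected pipeline
preserves enough geometry to classify the two profiles; protection
costs ≈ 0 accuracy at q = j−1. What they cannot show: performance on
real patients — real gait has pathology heterogeneity, camera
perspective effects, occlusions and pose-estimator biases that this
articulated model does not attempt.

## Classifier and ablation

The network is an LSTM (32 units) over the per-frame channel
sequences, dropout 0.3 on the hidden-state sequence, multiplicative
attention score(h_t, h_s) = h_tᵀWh_s with the final hidden state as
query and softmax-normalized scores pooling the states into a context
vector, a dense layer of 10 ReLU units with L1 penalty 0.002, and a
2-way softmax trained with cross-entropy under RMSProp (lr 10⁻³,
ρ 0.9). Epochs 100, batch 16, no early stopping — keeping both
ablation arms on an identical training schedule matters more than
squeezing either arm. The implementation is plain numpy with
hand-derived backpropagation-through-time; the unit tests verify every
parameter gradient against central finite differences (relative error
< 10⁻⁵) and that padding/masking is inert. Channels are z-scored with
train-fold statistics (in the protected arm, after protection — the
ML server normalizes what it receives).

Cross-validation is interpatient: folds draw 14 subjects per class for
training (the canonical count) or, for smaller cohorts, 70% of each
class, always leaving at least one test subject per class; no subject
ever appears on both sides of a fold. The ablation runs both arms on
identical folds, training seeds and initializations — asserted by a
fold fingerprint — with a fresh projection matrix seed per fold, and
reports per-metric protected − unprotected differences. The default
scaled-down study uses 10+10 subjects × 3 recordings of 120 frames
(4 s at 30 fps, matching a 4 m walk) and 5 folds; the protected arm
runs the true encrypted route at a 128-bit modulus.

## Known limitations

- The product-form private key is deliberately non-interoperable with
  lcm-convention Paillier libraries (same ciphertext space, different
  key files).
- A 128-bit modulus mirrors the deployment analyzed here but is far
  below modern factoring margins; the parameter is free.
- The greedy stroke extractor is a parameter-recovery tool, not a
  faithful reimplementation of clinical sigma-lognormal analyzers.
- The articulated walker is 2D and noise-stationary; it cannot stand
  in for real patient video beyond pipeline validation.
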