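"""Interpatient cross-validation and the protection ablation study.

The experiment design: subjects (never recordings) are split into
class-balanced train/test folds, the sequence classifier is trained
once per fold on unprotected per-frame gait channels and once on
channels protected by the hybrid scheme (Paillier encryption, Gaussian
random projection executed in the ciphertext domain, client-side
decryption of the projected template), with identical fold assignments
and training seeds in both arms and a fresh projection matrix per
fold.  The per-metric difference protected - unprotected quantifies
the accuracy cost of the protection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from . import paillier as pcrypt
from .features import extract_features
from .nn import LSTMAttentionClassifier, ModelConfig
from .projection import (
    ProjectionMatrix,
    generate_matrix,
    project_encrypted,
    quantize_matrix,
    decrypt_transformed,
)
from .synthetic import SyntheticCohort

__all__ = [
    "CVPlan",
    "MetricsReport",
    "AblationResult",
    "interpatient_split",
    "compute_metrics",
    "prepare_sequences",
    "protect_sequences",
    "run_ablation",
    "METRIC_NAMES",
]

METRIC_NAMES = ("precision", "sensitivity", "specificity", "f1", "accuracy", "auc_roc")


@dataclass(frozen=True)
class CVPlan:
    """Subject-disjoint cross-validation plan with per-fold seeds."""

    n_folds: int = 20
    train_per_class: int = 14
    seed: int = 0
    allow_fallback: bool = True

    @property
    def fold_seeds(self) -> tuple[int, ...]:
        ss = np.random.SeedSequence((self.seed, 0xF01D))
        return tuple(int(s) % (2**31) for s in ss.generate_state(self.n_folds))

    @property
    def projection_seeds(self) -> tuple[int, ...]:
        ss = np.random.SeedSequence((self.seed, 0x9801))
        return tuple(int(s) % (2**31) for s in ss.generate_state(self.n_folds))


@dataclass(frozen=True)
class MetricsReport:
    """Mean metrics (percent) across folds, with the per-fold values attached."""

    precision: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    auc_roc: float | None
    per_fold: tuple[dict, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class AblationResult:
    unprotected: MetricsReport
    protected: MetricsReport
    delta: dict
    fold_fingerprint: str


def interpatient_split(
    subject_labels: dict[str, str], plan: CVPlan
) -> list[tuple[set[str], set[str]]]:
    """Random class-balanced, subject-disjoint folds.

    Each fold draws ``train_per_class`` subjects from each class for
    training; everyone else tests.  Cohorts too small for that count fall
    back (when enabled) to a proportional draw of 70% of each class,
    mirroring the canonical 14-of-20 fraction, always leaving at least one
    test subject per class.
    """
    classes: dict[str, list[str]] = {}
    for subj in sorted(subject_labels):
        classes.setdefault(subject_labels[subj], []).append(subj)
    if len(classes) != 2:
        raise ValueError("interpatient split expects exactly two classes")
    folds = []
    for fold_seed in plan.fold_seeds:
        rng = np.random.default_rng(fold_seed)
        train: set[str] = set()
        test: set[str] = set()
        for label, members in sorted(classes.items()):
            k = plan.train_per_class
            if len(members) < k + 1:
                if not plan.allow_fallback:
                    raise ValueError(
                        f"class {label!r} has {len(members)} subjects; "
                        f"{k}+1 required without fallback"
                    )
                k = min(max(1, round(0.7 * len(members))), len(members) - 1)
            chosen = rng.choice(len(members), size=k, replace=False)
            chosen_ids = {members[i] for i in chosen}
            train |= chosen_ids
            test |= set(members) - chosen_ids
        folds.append((train, test))
    return folds


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> dict:
    """Confusion-matrix metrics at threshold 0.5 plus rank-based AUC, in percent."""
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if np.any((y_prob < 0) | (y_prob > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y_hat = (y_prob >= 0.5).astype(int)
    tp = int(np.sum((y_hat == 1) & (y_true == 1)))
    fp = int(np.sum((y_hat == 1) & (y_true == 0)))
    fn = int(np.sum((y_hat == 0) & (y_true == 1)))
    tn = int(np.sum((y_hat == 0) & (y_true == 0)))

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    precision = pct(tp, tp + fp)
    sensitivity = pct(tp, tp + fn)
    specificity = pct(tn, tn + fp)
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    accuracy = pct(tp + tn, tp + fp + fn + tn)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class fold: AUC ROC undefined", stacklevel=2)
        auc = None
    else:
        auc = 100.0 * float(roc_auc_score(y_true, y_prob))
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "accuracy": accuracy,
        "auc_roc": auc,
    }


def _summarize(per_fold: list[dict]) -> MetricsReport:
    means = {}
    for name in METRIC_NAMES:
        vals = [f[name] for f in per_fold if f[name] is not None]
        means[name] = float(np.mean(vals)) if vals else None
    return MetricsReport(per_fold=tuple(per_fold), **means)


# ---------------------------------------------------------------------------
# sequence preparation and protection


@dataclass(frozen=True)
class _PreparedRecording:
    subject_id: str
    label: int  # 1 = dementia
    channels: np.ndarray  # (T, n_channels)


def prepare_sequences(cohort: SyntheticCohort) -> list[_PreparedRecording]:
    """Run the feature pipeline on every recording; rows with NaN are dropped."""
    prepared = []
    for rec in cohort.recordings:
        kin, _, _ = extract_features(rec.seq)
        mat = kin.channels.to_numpy(dtype=float)
        mat = mat[np.isfinite(mat).all(axis=1)]
        prepared.append(
            _PreparedRecording(
                subject_id=rec.subject_id,
                label=1 if rec.class_label == "dementia" else 0,
                channels=mat,
            )
        )
    return prepared


def protect_sequences(
    recs: list[_PreparedRecording],
    M: ProjectionMatrix,
    prime_bits: int = 64,
    feat_scale: int = 6,
    mat_scale: int = 6,
    crypto_seed: int | None = None,
    encrypted: bool = True,
) -> list[_PreparedRecording]:
    """Apply the hybrid scheme to every frame of every recording.

    Each frame's channel vector is encrypted, projected in the ciphertext
    domain with the quantized matrix, and decrypted to the transformed
    vector.  ``encrypted=False`` short-circuits to the plaintext projection
    of the quantized values — bit-identical at the integer level to the
    encrypted route (a tested invariant) and useful when only the geometry
    matters.
    """
    Mq = quantize_matrix(M, mat_scale)
    if encrypted:
        import random as _random

        pub, priv = pcrypt.generate_keypair(prime_bits, crypto_seed=crypto_seed)
        enc_rng = _random.Random(crypto_seed if crypto_seed is not None else None)
    out = []
    deq = Mq.mantissas.astype(float)  # integer mantissas as floats for plain route
    for rec in recs:
        if encrypted:
            rows = []
            for frame in rec.channels:
                enc = [
                    pcrypt.encrypt(
                        pub, pcrypt.encode_real(v, feat_scale, pub.n), rng=enc_rng
                    )
                    for v in frame
                ]
                enc_y = project_encrypted(
                    enc, Mq, pub, max_abs_feature=float(np.abs(frame).max()) + 1.0
                )
                rows.append(decrypt_transformed(priv, enc_y).values)
            proj = np.array(rows)
        else:
            mant = np.rint(rec.channels * 10**feat_scale)
            proj = (mant @ deq) / 10 ** (feat_scale + mat_scale)
        out.append(replace(rec, channels=proj))
    return out


# ---------------------------------------------------------------------------
# ablation


def _standardize(train: list[np.ndarray], test: list[np.ndarray]):
    stacked = np.vstack(train)
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    return [(x - mu) / sd for x in train], [(x - mu) / sd for x in test]


def _train_eval(
    recs: list[_PreparedRecording],
    train_subjects: set[str],
    test_subjects: set[str],
    cfg: ModelConfig,
) -> dict:
    train = [r for r in recs if r.subject_id in train_subjects]
    test = [r for r in recs if r.subject_id in test_subjects]
    Xtr, Xte = _standardize([r.channels for r in train], [r.channels for r in test])
    model = LSTMAttentionClassifier(cfg, n_features=Xtr[0].shape[1])
    model.fit(Xtr, np.array([r.label for r in train]))
    prob = model.predict_proba(Xte)[:, 1]
    return compute_metrics(np.array([r.label for r in test]), prob)


def run_ablation(
    cohort: SyntheticCohort,
    cfg: ModelConfig | None = None,
    plan: CVPlan | None = None,
    proj_dim: int | None = None,
    prime_bits: int = 64,
    feat_scale: int = 6,
    mat_scale: int = 6,
    encrypted: bool = True,
    matrix_factory=generate_matrix,
) -> AblationResult:
    """Paired protected/unprotected cross-validation on one cohort.

    The two arms share fold assignments, training seeds and network
    initialization; the only difference is the insertion of the hybrid
    protection between feature extraction and the classifier.  A fresh
    projection matrix (new seed) is drawn for every fold.
    """
    cfg = cfg or ModelConfig()
    plan = plan or CVPlan()
    recs = prepare_sequences(cohort)
    j = recs[0].channels.shape[1]
    q = proj_dim if proj_dim is not None else j - 1
    folds = interpatient_split(cohort.subjects, plan)
    fingerprint_parts = []
    per_fold_u: list[dict] = []
    per_fold_p: list[dict] = []
    for f, (train_s, test_s) in enumerate(folds):
        fold_cfg = replace(cfg, train_seed=plan.fold_seeds[f])
        fingerprint_parts.append(
            f"{f}:{','.join(sorted(train_s))}|{fold_cfg.train_seed}"
        )
        per_fold_u.append(_train_eval(recs, train_s, test_s, fold_cfg))
        M = matrix_factory(j, q, plan.projection_seeds[f])
        protected = protect_sequences(
            recs, M, prime_bits=prime_bits, feat_scale=feat_scale,
            mat_scale=mat_scale, crypto_seed=plan.fold_seeds[f], encrypted=encrypted,
        )
        per_fold_p.append(_train_eval(protected, train_s, test_s, fold_cfg))
    import hashlib

    fingerprint = hashlib.sha256("#".join(fingerprint_parts).encode()).hexdigest()[:16]
    unprot = _summarize(per_fold_u)
    prot = _summarize(per_fold_p)
    delta = {
        name: (
            prot.as_dict()[name] - unprot.as_dict()[name]
            if prot.as_dict()[name] is not None and unprot.as_dict()[name] is not None
            else None
        )
        for name in METRIC_NAMES
    }
    return AblationResult(
        unprotected=unprot, protected=prot, delta=delta, fold_fingerprint=fingerprint
    )
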