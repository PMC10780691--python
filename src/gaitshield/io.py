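"""File formats: keys, ciphertext vectors, keypoints, features, metrics.

Big integers are hex-encoded in JSON; keypoints travel as long-form CSV
(recording_id, frame, keypoint_name, x, y, confidence) or an equivalent
per-frame JSON; projection matrices persist as seed + shape + scale only
(the entries are regenerable, and the seed is the secret).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import KEYPOINT_NAMES, KeypointSequence
from .paillier import Ciphertext, PaillierPrivateKey, PaillierPublicKey

__all__ = [
    "save_public_key",
    "load_public_key",
    "save_private_key",
    "load_private_key",
    "is_private_key_file",
    "save_ciphertext_vector",
    "load_ciphertext_vector",
    "save_keypoints_csv",
    "load_keypoints_csv",
    "save_keypoints_json",
    "load_keypoints_json",
    "save_matrix_sidecar",
    "load_matrix_sidecar",
]


def save_public_key(pub: PaillierPublicKey, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "kind": "paillier_public_key",
                "n": hex(pub.n),
                "g": hex(pub.g),
                "prime_bits": pub.prime_bits,
                "key_id": pub.key_id,
            },
            indent=1,
        )
    )


def load_public_key(path: str | Path) -> PaillierPublicKey:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "paillier_public_key":
        raise ValueError(f"{path} is not a public key file")
    return PaillierPublicKey(
        n=int(d["n"], 16), g=int(d["g"], 16), prime_bits=d["prime_bits"],
        key_id=d["key_id"],
    )


def save_private_key(priv: PaillierPrivateKey, path: str | Path) -> None:
    # client-only material; keep it out of server-side working directories
    Path(path).write_text(
        json.dumps(
            {
                "kind": "paillier_private_key",
                "lam": hex(priv.lam),
                "mu": hex(priv.mu),
                "n": hex(priv.n),
                "key_id": priv.key_id,
            },
            indent=1,
        )
    )


def load_private_key(path: str | Path) -> PaillierPrivateKey:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "paillier_private_key":
        raise ValueError(f"{path} is not a private key file")
    return PaillierPrivateKey(
        lam=int(d["lam"], 16), mu=int(d["mu"], 16), n=int(d["n"], 16),
        key_id=d["key_id"],
    )


def is_private_key_file(path: str | Path) -> bool:
    try:
        d = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError):
        return False
    return d.get("kind") == "paillier_private_key" or "lam" in d


def save_ciphertext_vector(cts: list[Ciphertext] | list[list[Ciphertext]], path: str | Path) -> None:
    """One JSON file per recording: a list of frames, each a ciphertext array."""

    def enc_one(c: Ciphertext) -> dict:
        return {"value_hex": hex(c.value), "scale_exp": c.scale_exp, "key_id": c.key_id}

    if cts and isinstance(cts[0], Ciphertext):
        payload = [enc_one(c) for c in cts]  # flat vector
    else:
        payload = [[enc_one(c) for c in frame] for frame in cts]
    Path(path).write_text(json.dumps(payload))


def load_ciphertext_vector(path: str | Path):
    raw = json.loads(Path(path).read_text())

    def dec_one(d: dict) -> Ciphertext:
        return Ciphertext(
            value=int(d["value_hex"], 16), scale_exp=d["scale_exp"], key_id=d["key_id"]
        )

    if raw and isinstance(raw[0], dict):
        return [dec_one(d) for d in raw]
    return [[dec_one(d) for d in frame] for frame in raw]


def save_keypoints_csv(
    seq: KeypointSequence, path: str | Path, recording_id: str = "rec0"
) -> None:
    rows = []
    for t in range(seq.n_frames):
        for k, name in enumerate(KEYPOINT_NAMES):
            x, y = seq.xy[t, k]
            rows.append(
                {
                    "recording_id": recording_id,
                    "frame": t,
                    "keypoint_name": name,
                    "x": "" if not np.isfinite(x) else x,
                    "y": "" if not np.isfinite(y) else y,
                    "confidence": seq.confidence[t, k],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_keypoints_csv(
    path: str | Path, dt: float = 1 / 30, subject_id: str = "", direction: str = "left_to_right"
) -> KeypointSequence:
    df = pd.read_csv(path)
    frames = sorted(df["frame"].unique())
    T = len(frames)
    xy = np.full((T, len(KEYPOINT_NAMES), 2), np.nan)
    conf = np.zeros((T, len(KEYPOINT_NAMES)))
    kp_index = {name: i for i, name in enumerate(KEYPOINT_NAMES)}
    for _, row in df.iterrows():
        t = int(row["frame"])
        name = row["keypoint_name"]
        if name not in kp_index:
            raise ValueError(f"unknown keypoint name {name!r}")
        k = kp_index[name]
        xy[t, k] = [row["x"], row["y"]]
        conf[t, k] = row["confidence"]
    return KeypointSequence.from_arrays(
        xy, dt=dt, confidence=conf, subject_id=subject_id, direction=direction
    )


def save_keypoints_json(
    seq: KeypointSequence, path: str | Path, recording_id: str = "rec0"
) -> None:
    frames = []
    for t in range(seq.n_frames):
        frames.append(
            {
                name: {
                    "x": None if not np.isfinite(seq.xy[t, k, 0]) else float(seq.xy[t, k, 0]),
                    "y": None if not np.isfinite(seq.xy[t, k, 1]) else float(seq.xy[t, k, 1]),
                    "confidence": float(seq.confidence[t, k]),
                }
                for k, name in enumerate(KEYPOINT_NAMES)
            }
        )
    Path(path).write_text(
        json.dumps({"recording_id": recording_id, "dt": seq.dt, "frames": frames})
    )


def load_keypoints_json(path: str | Path, subject_id: str = "", direction: str = "left_to_right") -> KeypointSequence:
    d = json.loads(Path(path).read_text())
    T = len(d["frames"])
    xy = np.full((T, len(KEYPOINT_NAMES), 2), np.nan)
    conf = np.zeros((T, len(KEYPOINT_NAMES)))
    for t, frame in enumerate(d["frames"]):
        for k, name in enumerate(KEYPOINT_NAMES):
            rec = frame.get(name)
            if rec is None:
                continue
            xy[t, k] = [
                np.nan if rec["x"] is None else rec["x"],
                np.nan if rec["y"] is None else rec["y"],
            ]
            conf[t, k] = rec.get("confidence", 0.0)
    return KeypointSequence.from_arrays(
        xy, dt=d.get("dt", 1 / 30), confidence=conf, subject_id=subject_id,
        direction=direction,
    )


def save_matrix_sidecar(j: int, q: int, seed: int, scale_exp: int, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"kind": "projection_matrix", "j": j, "q": q, "seed": seed,
                    "scale_exp": scale_exp})
    )


def load_matrix_sidecar(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "projection_matrix":
        raise ValueError(f"{path} is not a projection-matrix sidecar")
    return d
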