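"""Sigma-lognormal decomposition of movement speed profiles.

The kinematic theory of rapid human movements models any movement as a
superposition of primitives ("strokes") whose speed profile is a
lognormal in time:

    v(t) = D / (sigma * sqrt(2*pi) * (t - t0)) *
           exp(-(ln(t - t0) - mu)^2 / (2 * sigma^2)),    t > t0,

with amplitude D (the stroke's path length), onset time t0, log-time
delay mu and log-response-time sigma.  The decomposition here is the
classic greedy extraction: locate the dominant remaining speed mode,
fit a single lognormal to it by bounded nonlinear least squares, remove
it, and repeat until the residual energy is negligible or a stroke
budget is exhausted.  Start/end direction angles of each stroke are
read off the trajectory tangent angle at the stroke's 1st and 99th
percentile times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

__all__ = ["Stroke", "SigmaLognormalParams", "lognormal_profile", "sigma_lognormal_decompose"]


@dataclass(frozen=True)
class Stroke:
    D: float
    t0: float
    mu: float
    sigma: float
    theta_start: float
    theta_end: float

    def __post_init__(self) -> None:
        if self.D <= 0 or self.sigma <= 0:
            raise ValueError("stroke requires D > 0 and sigma > 0")


@dataclass(frozen=True)
class SigmaLognormalParams:
    strokes: tuple[Stroke, ...]

    @property
    def stroke_count(self) -> int:
        return len(self.strokes)


def lognormal_profile(
    t: np.ndarray, D: float, t0: float, mu: float, sigma: float
) -> np.ndarray:
    """Speed of one lognormal stroke on the grid t (zero at and before onset)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    tau = t - t0
    pos = tau > 0
    lt = np.log(tau[pos])
    out[pos] = (
        D / (sigma * np.sqrt(2 * np.pi) * tau[pos])
        * np.exp(-((lt - mu) ** 2) / (2 * sigma**2))
    )
    return out


def _fit_single_stroke(
    t: np.ndarray, target: np.ndarray, p: int
) -> tuple[float, float, float, float, float]:
    """Fit one stroke to the dominant mode at index p; returns params + cost."""
    v_p, t_p = target[p], t[p]
    # support of the mode: where the residual stays above 10% of the peak
    lo = p
    while lo > 0 and target[lo - 1] > 0.1 * v_p:
        lo -= 1
    hi = p
    while hi < len(t) - 1 and target[hi + 1] > 0.1 * v_p:
        hi += 1
    width = max(t[hi] - t[lo], t[1] - t[0])
    best = None
    t_floor = t[0] - 2.0 * max(width, 0.1)
    for sigma0 in (0.1, 0.2, 0.3, 0.5):
        # mode at t0 + exp(mu - sigma^2): anchor t0 a little before the support
        t0_0 = max(t[lo] - 0.2 * width, t_floor)
        if t0_0 >= t_p:
            t0_0 = t_p - width
        mu0 = np.log(max(t_p - t0_0, 1e-3)) + sigma0**2
        # peak height of the lognormal is D * exp(sigma^2/2 - mu) / (sigma sqrt(2 pi))
        D0 = v_p * sigma0 * np.sqrt(2 * np.pi) * np.exp(mu0 - sigma0**2 / 2)

        def resid(theta: np.ndarray) -> np.ndarray:
            D, t0, mu, sigma = theta
            return lognormal_profile(t, D, t0, mu, sigma) - target

        try:
            sol = least_squares(
                resid,
                x0=[max(D0, 1e-6), t0_0, mu0, sigma0],
                bounds=([1e-9, t_floor, -8.0, 0.01], [np.inf, t_p - 1e-6, 4.0, 2.0]),
                max_nfev=400,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best[1]:
            best = (sol.x, sol.cost)
    if best is None:
        raise RuntimeError("stroke fit failed for every initialization")
    (D, t0, mu, sigma), cost = best
    return float(D), float(t0), float(mu), float(sigma), float(cost)


def sigma_lognormal_decompose(
    speed: np.ndarray,
    t: np.ndarray,
    tangent_angle: np.ndarray | None = None,
    max_strokes: int = 8,
    residual_energy_frac: float = 0.02,
    peak_floor_frac: float = 0.05,
) -> SigmaLognormalParams:
    """Greedy lognormal stroke extraction from a non-negative speed profile.

    Strokes are extracted until the residual energy drops below
    ``residual_energy_frac`` of the original signal energy, no peak above
    ``peak_floor_frac`` of the original maximum remains, or ``max_strokes``
    is reached.  The time grid must be uniform.  An all-zero profile yields
    zero strokes.
    """
    speed = np.asarray(speed, dtype=float)
    t = np.asarray(t, dtype=float)
    if speed.shape != t.shape:
        raise ValueError("speed and t must have the same shape")
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    if len(t) >= 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
    total_energy = float(np.sum(speed**2))
    if total_energy == 0.0:
        return SigmaLognormalParams(strokes=())
    v_max = float(speed.max())
    residual = speed.copy()
    strokes: list[Stroke] = []
    while len(strokes) < max_strokes:
        if float(np.sum(np.maximum(residual, 0.0) ** 2)) < residual_energy_frac * total_energy:
            break
        p = int(np.argmax(residual))
        if residual[p] < peak_floor_frac * v_max:
            break
        D, t0, mu, sigma, _ = _fit_single_stroke(t, np.maximum(residual, 0.0), p)
        if D <= 0:
            break
        th_s, th_e = _stroke_angles(t, tangent_angle, t0, mu, sigma)
        strokes.append(
            Stroke(D=D, t0=t0, mu=mu, sigma=sigma, theta_start=th_s, theta_end=th_e)
        )
        residual = residual - lognormal_profile(t, D, t0, mu, sigma)
    strokes.sort(key=lambda s: s.t0 + np.exp(s.mu))
    return SigmaLognormalParams(strokes=tuple(strokes))


def _stroke_angles(
    t: np.ndarray,
    tangent_angle: np.ndarray | None,
    t0: float,
    mu: float,
    sigma: float,
) -> tuple[float, float]:
    """Trajectory direction at the stroke's 1st / 99th percentile times."""
    if tangent_angle is None:
        return 0.0, 0.0
    t_start = t0 + np.exp(mu + sigma * norm.ppf(0.01))
    t_end = t0 + np.exp(mu + sigma * norm.ppf(0.99))
    th_s = float(np.interp(t_start, t, tangent_angle))
    th_e = float(np.interp(t_end, t, tangent_angle))
    return th_s, th_e
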