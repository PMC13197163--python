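"""Circular statistics for directional-tuning analysis.

All public interfaces use degrees, with directions on [0, 360) and the
convention 0° = rightward, 90° = up, counterclockwise positive.  The
functions here back every directional computation in the package: the
first-harmonic cosine fit that yields local preferred directions (LPD)
and local motion sensitivities (LMS), the circular median used to pool
LPDs into a receptive-field preferred direction, the angular deviation
used as an exclusion criterion, and the Watson-Williams two-sample test
used to compare preferred directions between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "CosineFit",
    "CircularSummary",
    "WatsonWilliamsResult",
    "circ_mean",
    "circ_median",
    "circ_dispersion",
    "circ_distance",
    "fit_cosine",
    "watson_williams",
    "bonferroni_adjust",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class CosineFit:
    """First-harmonic fit R(theta) = baseline + amplitude*cos(theta - preferred_phase).

    ``preferred_phase`` is NaN (undefined) when the amplitude is zero to
    numerical precision: a flat tuning curve has no preferred direction.
    """

    baseline: float
    amplitude: float
    preferred_phase: float
    rms_residual: float

    @property
    def phase_defined(self) -> bool:
        return np.isfinite(self.preferred_phase)


@dataclass(frozen=True)
class CircularSummary:
    """Dispersion summary of an angle sample.

    ``circular_variance`` is the unitless 1 - R; ``angular_deviation`` is
    sqrt(2*(1 - R)) expressed in degrees, the quantity the receptive-field
    exclusion threshold (30°) is applied to.
    """

    mean_direction: float
    resultant_length: float
    median_direction: float
    circular_variance: float
    angular_deviation: float


@dataclass(frozen=True)
class WatsonWilliamsResult:
    F: float
    pvalue: float
    low_concentration: bool  # pooled resultant below the test's validity range


def _as_angles(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if a.ndim != 1:
        a = a.ravel()
    if a.size == 0:
        raise ValueError("angle sample must contain at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return np.mod(a, 360.0)


def _weights_for(a: np.ndarray, weights) -> np.ndarray:
    if weights is None:
        return np.ones_like(a)
    w = np.asarray(weights, dtype=float).ravel()
    if w.shape != a.shape:
        raise ValueError("weights must match angles in length")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must not all be zero")
    return w


def _wrap360(x: float) -> float:
    out = float(np.mod(x, 360.0))
    return 0.0 if out >= 360.0 else out


def circ_distance(a, b):
    """Unsigned circular distance between angles in degrees, on [0, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    return np.minimum(d, 360.0 - d)


def circ_mean(angles, weights=None) -> tuple[float, float]:
    """Weighted circular mean direction and resultant length.

    Returns ``(mean_direction_deg, R)`` where the mean is the argument of
    the (weighted) complex sum and R its normalised modulus in [0, 1].
    The mean is NaN when R vanishes (e.g. antipodal symmetry).
    """
    a = _as_angles(angles)
    w = _weights_for(a, weights)
    z = np.sum(w * np.exp(1j * np.deg2rad(a)))
    r = float(np.abs(z) / np.sum(w))
    r = min(r, 1.0)
    if r < 1e-12:
        return float("nan"), r
    return _wrap360(np.rad2deg(np.angle(z))), r


def _mean_circ_abs_dev(angles_rad: np.ndarray, m_rad) -> np.ndarray:
    """Mean circular absolute deviation d(m) = mean(pi - |pi - |theta - m||)."""
    m = np.atleast_1d(np.asarray(m_rad, dtype=float))
    d = np.mod(angles_rad[None, :] - m[:, None], _TWO_PI)
    dev = np.pi - np.abs(np.pi - d)
    return dev.mean(axis=1)


def circ_median(angles, weights=None) -> float:
    """Circular median: the direction minimising the mean circular absolute deviation.

    Candidates are restricted to the sample angles.  For odd n the best
    sample angle is returned; for even n the two central minimisers are
    averaged along their shorter arc.  Ties are broken toward the circular
    mean.  Weights are accepted for interface symmetry but the median is
    computed on the unweighted sample (matching the toolbox behaviour the
    field commonly relies on).
    """
    a = _as_angles(angles)
    a_rad = np.deg2rad(a)
    cand = np.unique(a_rad)
    dev = _mean_circ_abs_dev(a_rad, cand)

    mean_dir, r = circ_mean(a)
    ref = np.deg2rad(mean_dir) if np.isfinite(mean_dir) else 0.0

    def _tiebreak_key(theta):
        # smaller circular distance to the mean wins; then smaller angle
        d = np.mod(theta - ref, _TWO_PI)
        return (min(d, _TWO_PI - d), theta)

    order = sorted(range(cand.size), key=lambda i: (dev[i], *_tiebreak_key(cand[i])))
    if a.size % 2 == 1 or cand.size == 1:
        best = cand[order[0]]
        return _wrap360(np.rad2deg(best))

    # even n: circular midpoint of the two central minimisers, shorter arc
    t1, t2 = cand[order[0]], cand[order[1]]
    delta = np.mod(t2 - t1, _TWO_PI)
    if delta <= np.pi:
        mid = t1 + delta / 2.0
    else:
        mid = t2 + (_TWO_PI - delta) / 2.0
    if abs(delta - np.pi) < 1e-12:
        # antipodal pair: both midpoints equally good; pick the one nearer the mean
        m1, m2 = np.mod(mid, _TWO_PI), np.mod(mid + np.pi, _TWO_PI)
        mid = min((m1, m2), key=_tiebreak_key)
    return _wrap360(np.rad2deg(mid))


def circ_dispersion(angles, weights=None) -> CircularSummary:
    """Circular dispersion summary; requires at least two angles."""
    a = _as_angles(angles)
    if a.size < 2:
        raise ValueError("dispersion requires at least two angles")
    mean_dir, r = circ_mean(a, weights)
    variance = 1.0 - r
    ang_dev = float(np.rad2deg(np.sqrt(max(0.0, 2.0 * variance))))
    return CircularSummary(
        mean_direction=mean_dir,
        resultant_length=r,
        median_direction=circ_median(a, weights),
        circular_variance=variance,
        angular_deviation=ang_dev,
    )


def fit_cosine(directions, responses) -> CosineFit:
    """Least-squares first-harmonic fit for equally spaced directions.

    For n directions equally spaced over 360° the global least-squares fit
    of b + A*cos(theta - phi) has the closed form b = mean(responses),
    C = (2/n) * sum(responses * exp(i*theta)), A = |C|, phi = arg(C).
    The directional-tuning protocol samples 8 directions at 45° spacing.
    """
    th = np.asarray(directions, dtype=float).ravel()
    r = np.asarray(responses, dtype=float).ravel()
    if th.size != r.size:
        raise ValueError("directions and responses must have equal length")
    n = th.size
    if n < 3:
        raise ValueError("cosine fit requires at least 3 directions")
    order = np.argsort(np.mod(th, 360.0))
    th_s = np.mod(th, 360.0)[order]
    gaps = np.diff(np.concatenate([th_s, [th_s[0] + 360.0]]))
    if not np.allclose(gaps, 360.0 / n, atol=1e-6):
        raise ValueError("directions must be equally spaced over 360 degrees")

    b = float(np.mean(r))
    c = (2.0 / n) * np.sum(r * np.exp(1j * np.deg2rad(th)))
    amp = float(np.abs(c))
    scale = max(1.0, float(np.max(np.abs(r))) if r.size else 1.0)
    if amp <= 1e-12 * scale:
        amp_out, phase = 0.0, float("nan")
        pred = np.full_like(r, b)
    else:
        amp_out = amp
        phase = _wrap360(np.rad2deg(np.angle(c)))
        pred = b + amp * np.cos(np.deg2rad(th) - np.angle(c))
    rms = float(np.sqrt(np.mean((r - pred) ** 2)))
    return CosineFit(baseline=b, amplitude=amp_out, preferred_phase=phase, rms_residual=rms)


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood-style estimate of the von Mises concentration."""
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


def watson_williams(sample1, sample2) -> WatsonWilliamsResult:
    """Watson-Williams two-sample test for equal mean directions.

    Uses the concentration correction factor 1 + 3/(8*kappa) with kappa
    estimated from the pooled within-sample resultant length; p comes from
    the F distribution with (1, N-2) degrees of freedom.  When the pooled
    resultant is below the test's validity range (0.45) the result carries
    a ``low_concentration`` flag rather than raising, so pipelines do not
    abort on marginal data.
    """
    a1 = _as_angles(sample1)
    a2 = _as_angles(sample2)
    if a1.size < 2 or a2.size < 2:
        raise ValueError("each sample must contain at least two angles")
    n1, n2 = a1.size, a2.size
    n = n1 + n2
    r1 = np.abs(np.sum(np.exp(1j * np.deg2rad(a1))))
    r2 = np.abs(np.sum(np.exp(1j * np.deg2rad(a2))))
    r_all = np.abs(np.sum(np.exp(1j * np.deg2rad(np.concatenate([a1, a2])))))
    rw = (r1 + r2) / n  # pooled within-sample mean resultant
    low = bool(rw < 0.45)
    kappa = _kappa_from_r(min(rw, 1.0 - 1e-12))
    beta = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = n - (r1 + r2)
    if denom <= 1e-12:
        # both samples internally identical; any group difference is exact
        f = 0.0 if r_all >= (r1 + r2) - 1e-12 else float("inf")
    else:
        f = float(beta * ((n - 2) * (r1 + r2 - r_all)) / denom)
    f = max(f, 0.0)
    p = float(_sps.f.sf(f, 1, n - 2))
    return WatsonWilliamsResult(F=f, pvalue=p, low_concentration=low)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni adjustment min(1, m*p) for m comparisons."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be at least 1")
    return min(1.0, m * p)
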