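"""Tethered-flight kinematics: wingbeat amplitude, head angle and leg
extensions from keypoint tracking tables, with quality control.

The video pipeline films the fly from above at 100 Hz and tracks labelled
body parts (thorax axis, wing tips, two head points, fore- and hind-leg
points).  Wingbeat amplitude (WBA) of each wing is the unsigned angle
between the thorax axis and the vector from the anterior thorax point to
the wing tip.  Quality control removes (i) suspected tracking artefacts,
detected where plain and robust local-regression smoothings of the WBA
disagree by more than 5 % for over 1 s (the smoothing is used for error
detection only; analysis always runs on unsmoothed data), (ii) flight
stops, where either wing drops below 40° for at least 0.5 s, and (iii)
whole trials in which the animal was not flying for more than half the
trial.  Head and leg metrics inherit the WBA exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .responses import OnsetResult
from .stimuli import VelocitySchedule

__all__ = [
    "BODY_PARTS",
    "KeypointTrack",
    "WBASeries",
    "KinematicSummary",
    "loess",
    "wing_beat_amplitude",
    "qc_tracking_artifacts",
    "qc_flight_cessation",
    "qc_trial",
    "wbad_wbas",
    "head_angle",
    "leg_metrics",
    "kinematic_velocity_function",
    "response_onset_behaviour",
]

BODY_PARTS = (
    "thorax_anterior",
    "thorax_posterior",
    "wing_tip_L",
    "wing_tip_R",
    "head_1",
    "head_2",
    "foreleg_proximal_L",
    "foreleg_proximal_R",
    "foreleg_distal_L",
    "foreleg_distal_R",
    "hindleg_knee_L",
    "hindleg_knee_R",
    "abdomen_lateral_L",
    "abdomen_lateral_R",
)

KINEMATIC_METRICS = ("wbad", "wbas", "head_angle", "foreleg_extension",
                     "hindleg_extension", "hindleg_difference")


@dataclass(frozen=True)
class KeypointTrack:
    """Per-frame 2-D keypoints with optional likelihoods.

    ``data`` carries MultiIndex columns (bodypart, coordinate) with
    coordinates x, y and optionally likelihood; rows are frames at
    ``frame_rate`` Hz.
    """

    data: pd.DataFrame
    frame_rate: float = 100.0
    likelihood_floor: float = 0.6

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        idx = np.asarray(self.data.index, dtype=float)
        if idx.size > 1 and not np.allclose(np.diff(idx), idx[1] - idx[0]):
            raise ValueError("frame index must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def parts(self) -> tuple:
        return tuple(self.data.columns.get_level_values(0).unique())

    def xy(self, part: str) -> np.ndarray:
        if part not in self.data.columns.get_level_values(0):
            raise KeyError(f"body part {part!r} not in track")
        return self.data[part][["x", "y"]].to_numpy(dtype=float)

    def valid(self, part: str) -> np.ndarray:
        """Frames where the part's coordinates are finite and confident."""
        sub = self.data[part]
        ok = np.isfinite(sub["x"].to_numpy(float)) & np.isfinite(sub["y"].to_numpy(float))
        if "likelihood" in sub.columns:
            ok &= sub["likelihood"].to_numpy(float) >= self.likelihood_floor
        return ok


@dataclass
class WBASeries:
    """Per-frame wingbeat amplitudes with QC masks.

    ``qc_mask`` marks frames with usable tracking (True = valid);
    ``flight_mask`` marks frames where the animal is flying.
    """

    t: np.ndarray
    wba_L: np.ndarray
    wba_R: np.ndarray
    qc_mask: np.ndarray
    flight_mask: np.ndarray
    frame_rate: float = 100.0

    @property
    def valid(self) -> np.ndarray:
        return self.qc_mask & self.flight_mask


@dataclass(frozen=True)
class KinematicSummary:
    """Per-velocity medians of the kinematic metrics after stationary subtraction."""

    medians: pd.DataFrame      # index velocity, columns metrics
    n_reps: pd.DataFrame       # index velocity, columns metrics
    stationary: pd.Series      # per-metric mean at velocity 0 (subtracted)
    missing_velocities: tuple = ()


# ---------------------------------------------------------------------------
# local regression (loess) for the tracking-artifact rule

def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def loess(y, span: int = 51, degree: int = 2, robust: bool = False,
          iterations: int = 5) -> np.ndarray:
    """Local polynomial regression of a uniformly sampled series.

    Tricube distance weights over a centred window of ``span`` samples
    (truncated at the edges), local polynomials of ``degree``; the robust
    variant re-weights with Tukey's bisquare on the residuals for
    ``iterations`` passes, making it resistant to outliers.  NaNs are
    bridged by linear interpolation before smoothing.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if span < degree + 2:
        raise ValueError("span too small for the polynomial degree")
    if n < span:
        raise ValueError("series shorter than the smoother span")
    if np.any(~np.isfinite(y)):
        idx = np.arange(n)
        good = np.isfinite(y)
        if not np.any(good):
            raise ValueError("series is all-NaN")
        y = np.interp(idx, idx[good], y[good])
    half = span // 2
    x = np.arange(n, dtype=float)
    rw = np.ones(n)  # robustness weights
    fitted = y.copy()
    n_iter = 1 + (iterations if robust else 0)
    for it in range(n_iter):
        for i in range(n):
            lo = max(0, i - half)
            hi = min(n, i + half + 1)
            xi = x[lo:hi] - x[i]
            dmax = max(abs(xi[0]), abs(xi[-1]))
            w = _tricube(xi / dmax) * rw[lo:hi]
            if w.sum() <= 0:
                # every neighbour robust-rejected: fall back to distance
                # weights alone rather than leaving the point unfitted
                w = _tricube(xi / dmax)
            order = min(degree, np.count_nonzero(w) - 1)
            design = np.vander(xi, order + 1, increasing=True)
            wd = design * w[:, None]
            beta, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ y[lo:hi], rcond=None)
            fitted[i] = beta[0]
        if robust and it < n_iter - 1:
            resid = y - fitted
            s = np.median(np.abs(resid))
            # an (almost) interpolating fit leaves nothing to robustify;
            # a collapsed scale would otherwise zero every weight
            if s <= 1e-9 * max(1.0, float(np.max(np.abs(y)))):
                break
            rw = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return fitted


def _runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of maximal True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return
    edges = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e)


def qc_tracking_artifacts(
    values,
    frame_rate: float = 100.0,
    threshold: float = 0.05,
    min_duration: float = 1.0,
    span_s: float = 0.5,
    relative: bool = True,
    eps: float = 1.0,
) -> np.ndarray:
    """Flag suspected tracking artefacts (True = artefact frame).

    The series is smoothed with plain and robust loess of identical span;
    frames inside any maximal run where the discrepancy between the two
    exceeds ``threshold`` (5 %) for more than ``min_duration`` (1 s) are
    flagged.  With ``relative`` the discrepancy is |plain - robust| /
    max(|robust|, eps); otherwise it is in the signal's own units.
    """
    y = np.asarray(values, dtype=float).ravel()
    span = int(round(span_s * frame_rate))
    span += 1 - span % 2  # odd
    plain = loess(y, span=span, degree=2, robust=False)
    rob = loess(y, span=span, degree=2, robust=True)
    diff = np.abs(plain - rob)
    if relative:
        disc = diff / np.maximum(np.abs(rob), eps)
    else:
        disc = diff
    over = disc > threshold
    flagged = np.zeros(y.size, dtype=bool)
    min_frames = int(np.floor(min_duration * frame_rate))
    for s, e in _runs(over):
        if e - s > min_frames:
            flagged[s:e] = True
    return flagged


def qc_flight_cessation(
    wba_L,
    wba_R,
    frame_rate: float = 100.0,
    floor: float = 40.0,
    min_duration: float = 0.5,
) -> np.ndarray:
    """Flight mask (True = flying): runs where either wing's WBA stays
    below 40° for at least 0.5 s mark a cessation of flight."""
    lo = (np.asarray(wba_L, float) < floor) | (np.asarray(wba_R, float) < floor)
    flying = np.ones(lo.size, dtype=bool)
    min_frames = int(np.ceil(min_duration * frame_rate))
    for s, e in _runs(lo):
        if e - s >= min_frames:
            flying[s:e] = False
    return flying


def qc_trial(flight_mask, start: int | None = None, stop: int | None = None) -> bool:
    """Trial inclusion: keep unless the animal was not flying for more
    than 50 % of the trial (exactly 50 % is kept)."""
    m = np.asarray(flight_mask, dtype=bool)[start:stop]
    if m.size == 0:
        return False
    return bool(np.mean(~m) <= 0.5)


# ---------------------------------------------------------------------------
# geometry

def _body_axis(track: KeypointTrack) -> np.ndarray:
    """Unit vectors posterior -> anterior thorax per frame."""
    v = track.xy("thorax_anterior") - track.xy("thorax_posterior")
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return v / norm


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle (degrees) between row vectors of u and v."""
    dot = np.sum(u * v, axis=1)
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    return np.rad2deg(np.abs(np.arctan2(cross, dot)))


def wing_beat_amplitude(track: KeypointTrack) -> WBASeries:
    """Per-frame WBA of both wings.

    The WBA of a wing is the unsigned angle between the thorax axis
    (posterior -> anterior) and the vector from the anterior thorax point
    to the wing tip: 180° when the tip lies on the axis behind the
    thorax, 90° when perpendicular.  Frames with unusable keypoints are
    masked invalid.
    """
    for part in ("thorax_anterior", "thorax_posterior", "wing_tip_L", "wing_tip_R"):
        if part not in track.parts():
            raise KeyError(f"track missing required body part {part!r}")
    b = _body_axis(track)
    ant = track.xy("thorax_anterior")
    out = {}
    valid = (
        track.valid("thorax_anterior")
        & track.valid("thorax_posterior")
        & np.isfinite(b[:, 0])
    )
    masks = {}
    for side in ("L", "R"):
        tip = track.xy(f"wing_tip_{side}")
        w = tip - ant
        ok = valid & track.valid(f"wing_tip_{side}") & (np.linalg.norm(w, axis=1) > 0)
        ang = np.full(track.n_frames, np.nan)
        ang[ok] = _angle_between(b[ok], w[ok])
        out[side] = ang
        masks[side] = ok
    qc = masks["L"] & masks["R"]
    return WBASeries(
        t=track.t,
        wba_L=out["L"],
        wba_R=out["R"],
        qc_mask=qc,
        flight_mask=np.ones(track.n_frames, dtype=bool),
        frame_rate=track.frame_rate,
    )


def wbad_wbas(wba_L, wba_R, valid=None) -> tuple[float, float]:
    """WBA difference (left minus right) and sum over valid frames."""
    l = np.asarray(wba_L, dtype=float)
    r = np.asarray(wba_R, dtype=float)
    m = np.ones(l.size, dtype=bool) if valid is None else np.asarray(valid, bool)
    m = m & np.isfinite(l) & np.isfinite(r)
    if not np.any(m):
        return float("nan"), float("nan")
    return float(np.mean(l[m]) - np.mean(r[m])), float(np.mean(l[m]) + np.mean(r[m]))


def head_angle(track: KeypointTrack) -> tuple[np.ndarray, np.ndarray]:
    """Signed angle (degrees) between the head line and the thorax axis.

    The head line runs through the two tracked head points; the reported
    angle is folded into (-90°, 90°] since a line has no orientation.
    Positive means the head is rotated toward the animal's right in the
    dorsal view (with image y pointing down).  Frames with coincident
    head points are masked.
    """
    for part in ("head_1", "head_2", "thorax_anterior", "thorax_posterior"):
        if part not in track.parts():
            raise KeyError(f"track missing required body part {part!r}")
    b = _body_axis(track)
    h = track.xy("head_2") - track.xy("head_1")
    hn = np.linalg.norm(h, axis=1)
    ok = (
        track.valid("head_1") & track.valid("head_2")
        & track.valid("thorax_anterior") & track.valid("thorax_posterior")
        & np.isfinite(b[:, 0]) & (hn > 0)
    )
    ang = np.full(track.n_frames, np.nan)
    dot = np.sum(b * h, axis=1)
    cross = b[:, 0] * h[:, 1] - b[:, 1] * h[:, 0]
    raw = np.rad2deg(np.arctan2(cross, dot))
    folded = np.mod(raw + 90.0, 180.0) - 90.0
    folded[folded == -90.0] = 90.0
    ang[ok] = folded[ok]
    return ang, ok


def leg_metrics(track: KeypointTrack) -> pd.DataFrame:
    """Per-frame leg extensions (pixels, or calibrated units).

    Foreleg extension: proximal-to-distal distance, averaged over sides;
    hindleg extension: knee-to-lateral-abdomen distance, averaged over
    sides; hindleg difference: right minus left.  A side with unusable
    keypoints is dropped from the average (flagged ``*_partial``); the
    difference is undefined without both sides.  Hidden forelegs appear
    as NaN, not zero.
    """
    n = track.n_frames

    def side_distance(p1: str, p2: str) -> tuple[np.ndarray, np.ndarray]:
        d = np.linalg.norm(track.xy(p1) - track.xy(p2), axis=1)
        ok = track.valid(p1) & track.valid(p2)
        out = np.where(ok, d, np.nan)
        return out, ok

    fore_L, ok_fl = side_distance("foreleg_proximal_L", "foreleg_distal_L")
    fore_R, ok_fr = side_distance("foreleg_proximal_R", "foreleg_distal_R")
    hind_L, ok_hl = side_distance("hindleg_knee_L", "abdomen_lateral_L")
    hind_R, ok_hr = side_distance("hindleg_knee_R", "abdomen_lateral_R")

    with np.errstate(invalid="ignore"):
        fore = np.nanmean(np.column_stack([fore_L, fore_R]), axis=1)
        hind = np.nanmean(np.column_stack([hind_L, hind_R]), axis=1)
    diff = np.where(ok_hl & ok_hr, hind_R - hind_L, np.nan)
    return pd.DataFrame(
        {
            "foreleg_extension": fore,
            "hindleg_extension": hind,
            "hindleg_difference": diff,
            "foreleg_partial": ok_fl ^ ok_fr,
            "hindleg_partial": ok_hl ^ ok_hr,
        }
    )


def trial_metrics(track: KeypointTrack, apply_qc: bool = True,
                  **qc_kwargs) -> tuple[pd.DataFrame, np.ndarray, WBASeries]:
    """Per-frame metric table plus combined validity mask for one trial.

    Computes WBA, head angle and leg metrics, applies the tracking-
    artefact and flight-cessation rules to the WBA, and propagates the
    resulting exclusions to every metric.
    """
    wba = wing_beat_amplitude(track)
    if apply_qc:
        art = np.zeros(track.n_frames, dtype=bool)
        for series in (wba.wba_L, wba.wba_R):
            art |= qc_tracking_artifacts(series, frame_rate=track.frame_rate, **qc_kwargs)
        wba.qc_mask &= ~art
        wba.flight_mask = qc_flight_cessation(
            wba.wba_L, wba.wba_R, frame_rate=track.frame_rate
        )
    ha, ha_ok = head_angle(track)
    legs = leg_metrics(track)
    metrics = pd.DataFrame(
        {
            "wba_L": wba.wba_L,
            "wba_R": wba.wba_R,
            "head_angle": np.where(ha_ok, ha, np.nan),
            "foreleg_extension": legs["foreleg_extension"],
            "hindleg_extension": legs["hindleg_extension"],
            "hindleg_difference": legs["hindleg_difference"],
        }
    )
    valid = wba.valid
    return metrics, valid, wba


def kinematic_velocity_function(
    per_trial,
    schedules,
    frame_rate: float = 100.0,
    window: float = 1.0,
) -> KinematicSummary:
    """Velocity response functions of the kinematic metrics.

    ``per_trial`` is a list of (metrics DataFrame, valid mask) pairs, one
    per velocity trial, aligned with ``schedules``.  Trials failing the
    50 %-flight rule are dropped entirely.  For every step the mean of
    each metric over valid frames in the final ``window`` seconds forms
    one repetition; per velocity the median across repetitions is taken
    and the mean stationary (velocity 0) response subtracted.  WBAD/WBAS
    are derived from the per-frame wing columns before averaging.
    """
    if isinstance(schedules, VelocitySchedule):
        schedules = [schedules]
        per_trial = [per_trial]
    reps: dict[float, dict[str, list]] = {}
    for (metrics, valid), sched in zip(per_trial, schedules):
        valid = np.asarray(valid, dtype=bool)
        if not qc_trial(valid):
            continue
        for _, v, onset, dur in sched.steps():
            w = min(window, dur)
            i0 = int(round((onset + dur - w) * frame_rate))
            i1 = int(round((onset + dur) * frame_rate))
            sel = slice(max(i0, 0), min(i1, len(metrics)))
            sub = metrics.iloc[sel]
            ok = valid[sel]
            if not np.any(ok):
                continue
            sub = sub[ok]
            rec = reps.setdefault(float(v), {m: [] for m in KINEMATIC_METRICS})
            wbad, wbas = wbad_wbas(sub["wba_L"], sub["wba_R"])
            if np.isfinite(wbad):
                rec["wbad"].append(wbad)
                rec["wbas"].append(wbas)
            for m in ("head_angle", "foreleg_extension", "hindleg_extension",
                      "hindleg_difference"):
                vals = sub[m].to_numpy(dtype=float)
                if np.any(np.isfinite(vals)):
                    rec[m].append(float(np.nanmean(vals)))
    if not reps:
        raise ValueError("no valid repetitions in any trial")
    all_vel = sorted({v for s in schedules for v in s.velocities})
    missing = tuple(v for v in all_vel if v not in reps)
    velocities = sorted(reps)
    stationary = {}
    for m in KINEMATIC_METRICS:
        zero = reps.get(0.0, {}).get(m, [])
        stationary[m] = float(np.mean(zero)) if zero else 0.0
    med = pd.DataFrame(
        {
            m: [
                (np.median(reps[v][m]) - stationary[m]) if reps[v][m] else np.nan
                for v in velocities
            ]
            for m in KINEMATIC_METRICS
        },
        index=pd.Index(velocities, name="velocity"),
    )
    nrep = pd.DataFrame(
        {m: [len(reps[v][m]) for v in velocities] for m in KINEMATIC_METRICS},
        index=med.index,
    )
    return KinematicSummary(
        medians=med,
        n_reps=nrep,
        stationary=pd.Series(stationary),
        missing_velocities=missing,
    )


def response_onset_behaviour(
    t,
    values,
    stim_onset: float,
    duration: float = 2.0,
    mean_window: float = 1.0,
) -> OnsetResult:
    """Behavioural response onset by the 80 %-of-mean rule.

    The reference mean is taken over the final ``mean_window`` seconds of
    the step; onset is the first frame at or after stimulus onset whose
    value reaches 80 % of that mean.  Degenerate (non-positive) means are
    flagged undefined.
    """
    tt = np.asarray(t, dtype=float)
    vv = np.asarray(values, dtype=float)
    if tt.shape != vv.shape:
        raise ValueError("t and values must match")
    w0, w1 = stim_onset + duration - mean_window, stim_onset + duration
    in_mean = (tt >= w0 - 1e-9) & (tt < w1 - 1e-9)
    if not np.any(in_mean):
        raise ValueError("series does not cover the stimulus step")
    m = float(np.nanmean(vv[in_mean]))
    thresh = 0.8 * m
    win = (0.0, duration)
    if not np.isfinite(m) or m <= 0:
        return OnsetResult(float("nan"), thresh, win, degenerate=True)
    in_step = (tt >= stim_onset - 1e-9) & (tt < stim_onset + duration - 1e-9)
    idx = np.flatnonzero(in_step & (vv >= thresh - 1e-9 * max(1.0, abs(thresh))))
    if idx.size == 0:
        return OnsetResult(float("nan"), thresh, win)
    return OnsetResult(float(tt[idx[0]] - stim_onset), thresh, win)
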