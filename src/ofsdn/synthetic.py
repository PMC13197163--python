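"""Synthetic spiking and tracking data with known ground truth.

The generators emulate the statistical structure the analyses assume:
Poisson spiking with per-location cosine directional tuning under a
Gaussian spatial receptive-field envelope plus a spontaneous rate;
sigmoidal velocity tuning; and 100 Hz keypoint tracks whose derived
wingbeat, head and leg metrics follow configurable velocity responses
with latency, Gaussian noise, tracking-glitch artefacts and flight
stops.  Every generator is seeded and deterministic, and exposes the
generating parameters so recovery tests can compare against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import BODY_PARTS, KeypointTrack
from .receptive_field import RFGrid
from .stimuli import VelocitySchedule, make_velocity_schedule

__all__ = [
    "NeuronTemplate",
    "FlightTemplate",
    "class_template",
    "default_rf_lattice",
    "simulate_rf_protocol",
    "simulate_velocity_trial",
    "simulate_flight_track",
    "track_to_dlc_frame",
    "make_fixture_suite",
]

RF_DIRECTIONS = np.arange(0.0, 360.0, 45.0)


def default_rf_lattice() -> tuple[np.ndarray, np.ndarray]:
    """48 overlapping patch centres: 8 azimuths x 6 elevations, 20° apart
    (patches are ~38° wide, so neighbours overlap)."""
    return np.arange(-70.0, 71.0, 20.0), np.arange(-50.0, 51.0, 20.0)


@dataclass(frozen=True)
class NeuronTemplate:
    """Ground-truth model of one optic-flow-sensitive descending neuron.

    The local rate at patch p and direction theta is
    max(0, spontaneous + envelope(p) * max_lms * cos(theta - lpd(p))),
    with a Gaussian envelope of width ``rf_sigma`` about ``rf_centre``.
    ``lpd_field`` is ("uniform", phi0) or ("rotational", (az, el)), the
    latter giving directions tangent to circles about a flow centre (a
    roll-like field).  ``lpd_jitter`` adds per-location Gaussian jitter
    in degrees.  The velocity tuning is a signed Hill sigmoid
    g(v) = r_max * |v|^n / (|v|^n + v50^n) for the preferred sign, scaled
    by -``suppression`` for the anti-preferred sign.
    """

    neuron_class: str = "DN1_LHS"
    rf_centre: tuple[float, float] = (-40.0, 20.0)
    rf_sigma: float = 25.0
    max_lms: float = 100.0
    lpd_field: tuple = ("uniform", 150.0)
    lpd_jitter: float = 0.0
    spontaneous: float = 20.0
    r_max: float = 150.0
    v50: float = 0.4
    hill_n: float = 1.5
    preferred_sign: int = 1
    suppression: float = 0.3

    def __post_init__(self):
        if self.rf_sigma <= 0:
            raise ValueError("rf_sigma must be positive")
        if self.max_lms < 0 or self.spontaneous < 0:
            raise ValueError("max_lms and spontaneous must be non-negative")

    def envelope(self, azimuth, elevation) -> np.ndarray:
        a0, e0 = self.rf_centre
        d2 = (np.asarray(azimuth, float) - a0) ** 2 + (np.asarray(elevation, float) - e0) ** 2
        return np.exp(-d2 / (2.0 * self.rf_sigma**2))

    def lpd_at(self, azimuth: float, elevation: float) -> float:
        kind, par = self.lpd_field
        if kind == "uniform":
            return float(par) % 360.0
        if kind == "rotational":
            ca, ce = par
            radial = np.arctan2(elevation - ce, azimuth - ca)
            return float(np.rad2deg(radial) + 90.0) % 360.0
        raise ValueError(f"unknown lpd_field kind {kind!r}")

    def velocity_rate(self, v: float) -> float:
        """Evoked rate g(v) in spikes/s above spontaneous (may be negative)."""
        if v == 0:
            return 0.0
        mag = abs(v) ** self.hill_n
        sat = mag / (mag + self.v50**self.hill_n)
        if v * self.preferred_sign > 0:
            return float(self.r_max * sat)
        return float(-self.suppression * self.r_max * sat)

    def expected_response(self, v: float) -> float:
        """Expected stationary-subtracted response at velocity ``v``.

        Rates are floored at 0 before Poisson sampling, so the observable
        evoked rate is max(0, spontaneous + g(v)); the velocity-response
        pipeline subtracts the stationary (v = 0) value.
        """
        evoked = max(0.0, self.spontaneous + self.velocity_rate(v))
        stationary = max(0.0, self.spontaneous + self.velocity_rate(0.0))
        return float(evoked - stationary)


#: Per-class template parameters: preferred direction well inside the
#: classification band, receptive-field centre on the matching side.
_CLASS_PARAMS = {
    "DN1_LHS": {"lpd_field": ("uniform", 150.0), "rf_centre": (-40.0, 20.0)},
    "DN1_RHS": {"lpd_field": ("uniform", 30.0), "rf_centre": (40.0, 20.0)},
    "DN2_LHS": {"lpd_field": ("uniform", 270.0), "rf_centre": (-35.0, 0.0)},
    "DN2_RHS": {"lpd_field": ("uniform", 270.0), "rf_centre": (35.0, 0.0)},
}


def class_template(neuron_class: str, **overrides) -> NeuronTemplate:
    """Template for one of the four neuron classes, optionally overridden."""
    if neuron_class not in _CLASS_PARAMS:
        raise ValueError(f"unknown neuron class {neuron_class!r}")
    params = dict(_CLASS_PARAMS[neuron_class], neuron_class=neuron_class)
    params.update(overrides)
    return NeuronTemplate(**params)


def simulate_rf_protocol(
    template: NeuronTemplate,
    reps: int = 5,
    duration: float = 0.36,
    seed: int | None = None,
    noiseless: bool = False,
    azimuths=None,
    elevations=None,
) -> RFGrid:
    """Simulate the receptive-field mapping protocol for one neuron.

    48 patch locations x 8 directions x ``reps`` presentations of
    ``duration`` seconds; spike counts are Poisson with the template's
    local rate (floored at 0).  ``noiseless`` returns expected rates
    instead of sampled ones, for exact recovery checks.
    """
    az, el = default_rf_lattice() if azimuths is None else (
        np.asarray(azimuths, float), np.asarray(elevations, float))
    rng = np.random.default_rng(seed)
    rates = np.zeros((el.size, az.size, RF_DIRECTIONS.size))
    for i, e in enumerate(el):
        for j, a in enumerate(az):
            env = float(template.envelope(a, e))
            lpd = template.lpd_at(a, e)
            if template.lpd_jitter > 0:
                lpd = (lpd + rng.normal(0.0, template.lpd_jitter)) % 360.0
            lam = np.maximum(
                0.0,
                template.spontaneous
                + env * template.max_lms * np.cos(np.deg2rad(RF_DIRECTIONS - lpd)),
            )
            if noiseless:
                rates[i, j, :] = lam
            else:
                counts = rng.poisson(lam * duration, size=(reps, RF_DIRECTIONS.size))
                rates[i, j, :] = counts.mean(axis=0) / duration
    return RFGrid(
        azimuths=az,
        elevations=el,
        directions=RF_DIRECTIONS,
        rates=rates,
        spontaneous=template.spontaneous,
    )


def rf_protocol_table(grid: RFGrid, neuron_id: str = "n0",
                      duration: float = 0.36) -> pd.DataFrame:
    """Flatten a simulated grid to the tidy response-table schema."""
    rows = []
    for i, e in enumerate(grid.elevations):
        for j, a in enumerate(grid.azimuths):
            for k, d in enumerate(grid.directions):
                rows.append(
                    (neuron_id, a, e, d, 0, grid.rates[i, j, k] * duration, duration)
                )
    return pd.DataFrame(
        rows,
        columns=["neuron_id", "location_azimuth", "location_elevation",
                 "direction", "repetition", "spike_count", "duration_s"],
    )


def _piecewise_poisson(segments, rng) -> np.ndarray:
    """Spike times of an inhomogeneous Poisson process with piecewise-
    constant rate; ``segments`` yields (t0, duration, rate)."""
    times = []
    for t0, dur, rate in segments:
        lam = max(rate, 0.0) * dur
        n = rng.poisson(lam)
        if n:
            times.append(np.sort(rng.uniform(t0, t0 + dur, size=n)))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def simulate_velocity_trial(
    template: NeuronTemplate,
    schedule: VelocitySchedule,
    seed: int | None = None,
    transient_gain: float = 0.0,
    transient_duration: float = 0.1,
) -> np.ndarray:
    """Spike times for one velocity-step trial (seconds from trial start).

    Rate is spontaneous during the pre-stimulus blank and
    spontaneous + g(v) during each step; an optional multiplicative
    onset transient boosts the first ``transient_duration`` seconds of
    each step by ``transient_gain``.
    """
    rng = np.random.default_rng(seed)
    segs = [(0.0, schedule.pre_stim, template.spontaneous)]
    for _, v, onset, dur in schedule.steps():
        rate = template.spontaneous + template.velocity_rate(v)
        if transient_gain > 0 and dur > transient_duration:
            segs.append((onset, transient_duration, rate * (1.0 + transient_gain)))
            segs.append((onset + transient_duration, dur - transient_duration, rate))
        else:
            segs.append((onset, dur, rate))
    return _piecewise_poisson(segs, rng)


@dataclass(frozen=True)
class FlightTemplate:
    """Ground truth for a tethered-flight keypoint track.

    WBA baselines sit above the 40° flight floor; responses to the
    scheduled velocity follow a signed Hill sigmoid s(v) in [-1, 1] with
    the stated ``latency``.  ``artefact_blocks`` receive alternating
    +-``artefact_amplitude`` jitter on the left wing (a tracking glitch);
    ``stops`` drop both wings to ``stop_wba`` (flight cessation).
    """

    wba_base_L: float = 55.0
    wba_base_R: float = 55.0
    wbas_gain: float = 14.0
    wbad_gain: float = 8.0
    head_gain: float = 6.0
    foreleg_base: float = 20.0
    foreleg_gain: float = 12.0
    hindleg_base: float = 40.0
    hindleg_gain: float = 10.0
    hindleg_diff_gain: float = 8.0
    latency: float = 0.3
    v50: float = 0.4
    hill_n: float = 1.5
    noise_sd: float = 1.0
    artefact_blocks: tuple = ()
    artefact_amplitude: float = 30.0
    stops: tuple = ()
    stop_wba: float = 30.0

    def sigmoid(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        mag = np.abs(v) ** self.hill_n
        return np.sign(v) * mag / (mag + self.v50**self.hill_n)


def _rot(deg):
    r = np.deg2rad(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


def simulate_flight_track(
    template: FlightTemplate,
    schedule: VelocitySchedule,
    seed: int | None = None,
    frame_rate: float = 100.0,
) -> tuple[KeypointTrack, pd.DataFrame]:
    """Generate a 100 Hz keypoint track for one velocity trial.

    Returns the track plus a per-frame ground-truth table (wba_L, wba_R,
    head_angle, foreleg_extension, hindleg_extension, hindleg_difference)
    before keypoint construction, for recovery tests.
    """
    rng = np.random.default_rng(seed)
    n = int(round(schedule.total_duration * frame_rate))
    t = np.arange(n) / frame_rate

    # velocity seen by the response, delayed by the template latency
    v = np.zeros(n)
    for _, vel, onset, dur in schedule.steps():
        sel = (t >= onset + template.latency) & (t < onset + dur + template.latency)
        v[sel] = vel
    s = template.sigmoid(v)

    wbas_delta = template.wbas_gain * np.abs(s)
    wbad_delta = template.wbad_gain * s
    wba_L = template.wba_base_L + (wbas_delta + wbad_delta) / 2.0
    wba_R = template.wba_base_R + (wbas_delta - wbad_delta) / 2.0
    wba_L = wba_L + rng.normal(0.0, template.noise_sd, n)
    wba_R = wba_R + rng.normal(0.0, template.noise_sd, n)
    for t0, t1 in template.stops:
        sel = (t >= t0) & (t < t1)
        wba_L[sel] = template.stop_wba
        wba_R[sel] = template.stop_wba
    # tracking glitches are one-sided jumps (a keypoint snaps to a wrong
    # position on some frames), not zero-mean jitter; zero-mean jitter is
    # invisible to the loess-vs-robust-loess discrepancy rule because both
    # smoothers average it away
    for t0, t1 in template.artefact_blocks:
        sel = np.flatnonzero((t >= t0) & (t < t1))
        wba_L[sel] += template.artefact_amplitude * (sel % 2 == 0)

    head = template.head_gain * s + rng.normal(0.0, 0.3 * template.noise_sd, n)
    head = np.clip(head, -80.0, 80.0)
    fore = template.foreleg_base + template.foreleg_gain * np.abs(s)
    fore = fore + rng.normal(0.0, 0.2 * template.noise_sd, n)
    hind = template.hindleg_base + template.hindleg_gain * np.abs(s)
    hind = hind + rng.normal(0.0, 0.2 * template.noise_sd, n)
    hdiff = template.hindleg_diff_gain * s + rng.normal(0.0, 0.2 * template.noise_sd, n)

    truth = pd.DataFrame(
        {
            "t": t,
            "velocity": v,
            "wba_L": wba_L,
            "wba_R": wba_R,
            "head_angle": head,
            "foreleg_extension": fore,
            "hindleg_extension": hind,
            "hindleg_difference": hdiff,
        }
    )

    # --- keypoint construction (image coordinates, y down, dorsal view) ---
    ant = np.array([200.0, 180.0])
    post = np.array([200.0, 220.0])
    b_hat = (ant - post) / np.linalg.norm(ant - post)  # (0, -1): facing up-image
    wing_len = 60.0
    cols = {}

    def set_part(name, pts):
        cols[(name, "x")] = pts[:, 0]
        cols[(name, "y")] = pts[:, 1]
        cols[(name, "likelihood")] = np.ones(n)

    set_part("thorax_anterior", np.tile(ant, (n, 1)))
    set_part("thorax_posterior", np.tile(post, (n, 1)))
    for side, wba, sgn in (("L", wba_L, -1.0), ("R", wba_R, 1.0)):
        ang = np.deg2rad(sgn * wba)
        dirs = np.column_stack(
            [b_hat[0] * np.cos(ang) - b_hat[1] * np.sin(ang),
             b_hat[0] * np.sin(ang) + b_hat[1] * np.cos(ang)]
        )
        set_part(f"wing_tip_{side}", ant + wing_len * dirs)
    # head line through two points, rotated by the head angle
    h0 = ant + 15.0 * b_hat
    ang = np.deg2rad(head)
    hd = np.column_stack(
        [b_hat[0] * np.cos(ang) - b_hat[1] * np.sin(ang),
         b_hat[0] * np.sin(ang) + b_hat[1] * np.cos(ang)]
    )
    set_part("head_1", h0 - 8.0 * hd)
    set_part("head_2", h0 + 8.0 * hd)
    # legs: place distal/knee points at the target distances
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        u = np.array([sgn * 0.8, -0.6])
        prox = post + np.array([sgn * 12.0, -20.0])
        set_part(f"foreleg_proximal_{side}", np.tile(prox, (n, 1)))
        set_part(f"foreleg_distal_{side}", prox + fore[:, None] * u)
        abd = post + np.array([sgn * 10.0, 15.0])
        hind_side = hind + sgn * hdiff / 2.0  # R - L = hdiff
        set_part(f"abdomen_lateral_{side}", np.tile(abd, (n, 1)))
        v_leg = np.array([sgn * 0.7, 0.714142842854285])
        v_leg = v_leg / np.linalg.norm(v_leg)
        set_part(f"hindleg_knee_{side}", abd + hind_side[:, None] * v_leg)

    data = pd.DataFrame(cols)
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["bodypart", "coordinate"])
    return KeypointTrack(data=data, frame_rate=frame_rate), truth


def track_to_dlc_frame(track: KeypointTrack, scorer: str = "ofsdn_synth") -> pd.DataFrame:
    """Re-shape a track into a DLC-dialect table (scorer/bodypart/coordinate)."""
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, part, coord) for part, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    return df


def make_fixture_suite(seed: int, outdir, n_velocities: int = 5,
                       repetitions: int = 2, step_duration: float = 2.0) -> dict:
    """Write a small deterministic fixture bundle with ground truth.

    Produces the four clean neuron classes plus three excludable
    variants (low LMS, few supra-half positions, high LPD dispersion) as
    tidy response tables, and two flight animals x two axes as DLC-style
    keypoint CSVs with matching schedules.  Returns the ground-truth
    dictionary, also written to ``ground_truth.json``.
    """
    out = Path(outdir)
    (out / "neurons").mkdir(parents=True, exist_ok=True)
    (out / "flight").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"seed": int(seed), "neurons": {}, "flight": {}}

    variants = {
        cls: class_template(cls) for cls in _CLASS_PARAMS
    }
    variants["excl_low_lms"] = class_template("DN1_LHS", max_lms=8.0)
    variants["excl_few_positions"] = class_template("DN1_LHS", rf_sigma=7.0)
    variants["excl_high_dispersion"] = class_template("DN1_LHS", lpd_jitter=80.0)

    for name, tpl in variants.items():
        sub = int(rng.integers(0, 2**31 - 1))
        grid = simulate_rf_protocol(tpl, reps=5, seed=sub)
        table = rf_protocol_table(grid, neuron_id=name)
        table.to_csv(out / "neurons" / f"{name}.csv", index=False)
        truth["neurons"][name] = {
            "class": tpl.neuron_class,
            "excludable": name.startswith("excl"),
            "spontaneous": tpl.spontaneous,
            "max_lms": tpl.max_lms,
            "seed": sub,
        }
    pd.DataFrame(
        [(name, v["spontaneous"]) for name, v in truth["neurons"].items()],
        columns=["neuron_id", "spontaneous_rate"],
    ).to_csv(out / "neurons" / "spontaneous.csv", index=False)

    velocities = np.linspace(-2.0, 2.0, n_velocities)
    for animal in ("animal1", "animal2"):
        for axis in ("sideslip", "lift"):
            sub = int(rng.integers(0, 2**31 - 1))
            sched = make_velocity_schedule(
                velocities, repetitions=repetitions,
                step_duration=step_duration, axis=axis, seed=sub,
            )
            tpl = FlightTemplate()
            track, _ = simulate_flight_track(tpl, sched, seed=sub + 1)
            name = f"{animal}_{axis}"
            track_to_dlc_frame(track).to_csv(out / "flight" / f"{name}.csv")
            sched_df = pd.DataFrame(
                [(i, v, "m/s", t0, d) for i, v, t0, d in sched.steps()],
                columns=["index", "velocity", "units", "onset_s", "duration_s"],
            )
            sched_df.to_csv(out / "flight" / f"{name}_schedule.csv", index=False)
            truth["flight"][name] = {
                "axis": axis,
                "latency": tpl.latency,
                "wbas_gain": tpl.wbas_gain,
                "seed": sub,
            }

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
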