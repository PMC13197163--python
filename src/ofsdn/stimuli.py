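"""Mathematics of the visual stimuli: perspective-corrected starfields,
velocity-step schedules, gratings and screen geometry.

Frame convention (fly-centred, metres): x right, y forward, z up.
Ego-motion is simulated as the inverse transform of the scene points:
positive thrust makes points recede along +y, positive sideslip moves
the image leftward (points shift along -x), positive lift moves the
image downward (points shift along -z); rotations rotate the scene by
-omega*dt about roll = y (forward), pitch = x (transverse), yaw = z
(vertical), so that positive roll appears counterclockwise on screen.
No rendering happens here: the module emits per-frame geometry only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "TRANSLATION_AXES",
    "ROTATION_AXES",
    "ScreenGeometry",
    "MotionSpec",
    "Starfield",
    "VelocitySchedule",
    "GratingSpec",
    "visual_angle",
    "default_velocity_lists",
    "make_velocity_schedule",
    "seed_starfield",
    "propagate_starfield",
    "project_to_screen",
    "max_displacement_check",
    "grating_spec",
]

TRANSLATION_AXES = ("sideslip", "lift", "thrust")
ROTATION_AXES = ("roll", "pitch", "yaw")

# Unit vector u per axis such that a positive velocity v displaces scene
# points by -v*dt*u (translations) or rotates them by -omega*dt about u.
_TRANSLATION_UNIT = {
    "sideslip": np.array([1.0, 0.0, 0.0]),   # +v -> image moves leftward
    "lift": np.array([0.0, 0.0, 1.0]),       # +v -> image moves downward
    "thrust": np.array([0.0, -1.0, 0.0]),    # +v -> points recede along +y
}
_ROTATION_UNIT = {
    "roll": np.array([0.0, 1.0, 0.0]),
    "pitch": np.array([1.0, 0.0, 0.0]),
    "yaw": np.array([0.0, 0.0, 1.0]),
}


@dataclass(frozen=True)
class ScreenGeometry:
    """Flat screen facing the fly, plane at y = ``distance``, square pixels."""

    distance: float = 0.065
    width_px: int = 2560
    height_px: int = 1440
    width_m: float = 0.58
    height_m: float = 0.33
    refresh: float = 165.0

    def __post_init__(self):
        for name in ("distance", "width_px", "height_px", "width_m", "height_m", "refresh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def field_of_view(self) -> tuple[float, float]:
        """(horizontal, vertical) projected visual field in degrees."""
        return (
            visual_angle(self.width_m, self.distance),
            visual_angle(self.height_m, self.distance),
        )


@dataclass(frozen=True)
class MotionSpec:
    """One self-motion axis and velocity (m/s translations, deg/s rotations)."""

    axis: str
    velocity: float

    def __post_init__(self):
        if self.axis not in TRANSLATION_AXES + ROTATION_AXES:
            raise ValueError(f"unknown axis {self.axis!r}")

    @property
    def is_rotation(self) -> bool:
        return self.axis in ROTATION_AXES

    @property
    def units(self) -> str:
        return "deg/s" if self.is_rotation else "m/s"


@dataclass(frozen=True)
class Starfield:
    """Random field of small spheres in an axis-aligned box (metres)."""

    points: np.ndarray  # (N, 3)
    sphere_diameter: float = 0.02
    volume: tuple[float, float, float, float, float, float] = (-1.0, 1.0, -1.0, 1.0, -1.0, 1.0)
    seed: int | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be positive")
        x0, x1, y0, y1, z0, z1 = self.volume
        if not (x1 > x0 and y1 > y0 and z1 > z0):
            raise ValueError("volume must have positive extent on every axis")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class VelocitySchedule:
    """Ordered velocity steps preceded by a blank pre-stimulus interval."""

    entries: tuple  # of (velocity, duration_s)
    axis: str = "roll"
    pre_stim: float = 1.0
    seed: int | None = None

    @property
    def velocities(self) -> np.ndarray:
        return np.array([v for v, _ in self.entries], dtype=float)

    @property
    def onsets(self) -> np.ndarray:
        durs = np.array([d for _, d in self.entries], dtype=float)
        return self.pre_stim + np.concatenate([[0.0], np.cumsum(durs[:-1])])

    @property
    def total_duration(self) -> float:
        return self.pre_stim + float(sum(d for _, d in self.entries))

    def steps(self):
        """Yield (index, velocity, onset_s, duration_s) for each step."""
        for i, ((v, d), t0) in enumerate(zip(self.entries, self.onsets)):
            yield i, v, float(t0), float(d)


@dataclass(frozen=True)
class GratingSpec:
    """Sinusoidal grating; drift speed = temporal_frequency * wavelength."""

    wavelength: float
    temporal_frequency: float = 5.0
    contrast: float = 1.0
    direction: float = 0.0
    duration: float = 1.0
    extent: str | float = "full"

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def spatial_frequency(self) -> float:
        return 1.0 / self.wavelength

    @property
    def drift_speed(self) -> float:
        return self.temporal_frequency * self.wavelength


def visual_angle(extent_m: float, distance_m: float) -> float:
    """Visual angle (degrees) subtended by a flat extent at a viewing distance."""
    if distance_m <= 0:
        raise ValueError("distance must be positive")
    if extent_m < 0:
        raise ValueError("extent must be non-negative")
    return float(np.rad2deg(2.0 * np.arctan(extent_m / (2.0 * distance_m))))


def default_velocity_lists(literal_rotations: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """The protocol's 13-entry translation (m/s) and rotation (deg/s) lists.

    The default rotation list is symmetric, running -200 ... +200 deg/s.
    ``literal_rotations=True`` instead returns the dialect whose first
    entry is +200 (documented historical form, asymmetric).
    """
    translations = np.array(
        [-2.0, -1.5, -1.0, -0.4, -0.2, -0.1, 0.0, 0.1, 0.2, 0.4, 1.0, 1.5, 2.0]
    )
    first = 200.0 if literal_rotations else -200.0
    rotations = np.array(
        [first, -150.0, -100.0, -40.0, -20.0, -10.0, 0.0, 10.0, 20.0, 40.0, 100.0, 150.0, 200.0]
    )
    return translations, rotations


def make_velocity_schedule(
    velocities,
    repetitions: int = 3,
    step_duration: float = 2.0,
    pre_stim: float = 1.0,
    axis: str = "roll",
    seed: int | None = None,
) -> VelocitySchedule:
    """Uniformly random permutation (seeded) of velocities x repetitions.

    Steps follow one another immediately; the protocol presents 13 unique
    velocities three times each (39 presentations of 2 s) after a 1-s blank.
    """
    v = np.asarray(velocities, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("velocity list must not be empty")
    if repetitions < 1:
        raise ValueError("repetitions must be at least 1")
    if step_duration <= 0 or pre_stim < 0:
        raise ValueError("durations must be positive")
    multiset = np.repeat(v, repetitions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(multiset.size)
    entries = tuple((float(multiset[i]), float(step_duration)) for i in perm)
    return VelocitySchedule(entries=entries, axis=axis, pre_stim=pre_stim, seed=seed)


def seed_starfield(
    volume,
    density: float,
    sphere_diameter: float = 0.02,
    seed: int | None = None,
) -> Starfield:
    """Independent uniform sphere centres; count = round(density * box volume)."""
    x0, x1, y0, y1, z0, z1 = (float(v) for v in volume)
    vol = (x1 - x0) * (y1 - y0) * (z1 - z0)
    if vol <= 0:
        raise ValueError("volume must be positive")
    if density < 0:
        raise ValueError("density must be non-negative")
    n = int(round(density * vol))
    rng = np.random.default_rng(seed)
    pts = rng.uniform([x0, y0, z0], [x1, y1, z1], size=(n, 3))
    return Starfield(points=pts, sphere_diameter=sphere_diameter,
                     volume=(x0, x1, y0, y1, z0, z1), seed=seed)


def _wrap_into_box(points: np.ndarray, volume) -> np.ndarray:
    x0, x1, y0, y1, z0, z1 = volume
    lo = np.array([x0, y0, z0])
    hi = np.array([x1, y1, z1])
    return np.mod(points - lo, hi - lo) + lo


def propagate_starfield(
    field: Starfield, motion: MotionSpec, dt: float, wrap: bool = True
) -> Starfield:
    """Advance the scene by one ego-motion step of duration ``dt``.

    Translations displace every point by -v*dt along the axis unit vector;
    rotations apply a rigid rotation by -omega*dt about the axis through
    the origin (the eye).  With ``wrap`` points leaving the box re-enter
    on the opposite face, keeping the density stationary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pts = field.points
    if motion.is_rotation:
        u = _ROTATION_UNIT[motion.axis]
        ang = -np.deg2rad(motion.velocity * dt)
        new = Rotation.from_rotvec(ang * u).apply(pts) if pts.size else pts.copy()
    else:
        u = _TRANSLATION_UNIT[motion.axis]
        new = pts - motion.velocity * dt * u
    if wrap:
        new = _wrap_into_box(new, field.volume)
    return Starfield(points=new, sphere_diameter=field.sphere_diameter,
                     volume=field.volume, seed=field.seed)


def project_to_screen(field: Starfield, geom: ScreenGeometry) -> np.ndarray:
    """Pinhole projection onto the screen plane at y = distance.

    Returns an array of rows (point_index, x_px, y_px, angular_diameter_deg)
    for points in front of the eye and inside the screen frustum.  The
    angular diameter of a sphere of radius r at range D is 2*asin(r/D);
    points at or inside one sphere radius of the eye are culled.
    """
    pts = field.points
    r = field.sphere_diameter / 2.0
    if pts.size == 0:
        return np.empty((0, 4))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    dist = np.linalg.norm(pts, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(y > 0, x * geom.distance / y, np.nan)
        v = np.where(y > 0, z * geom.distance / y, np.nan)
    visible = (
        (y > 0)
        & (dist > r)
        & (np.abs(u) <= geom.width_m / 2.0)
        & (np.abs(v) <= geom.height_m / 2.0)
    )
    idx = np.nonzero(visible)[0]
    x_px = geom.width_px / 2.0 + u[idx] * geom.width_px / geom.width_m
    y_px = geom.height_px / 2.0 + v[idx] * geom.height_px / geom.height_m
    ang = np.rad2deg(2.0 * np.arcsin(r / dist[idx]))
    return np.column_stack([idx.astype(float), x_px, y_px, ang])


def max_displacement_check(
    motion: MotionSpec, geom: ScreenGeometry, field: Starfield
) -> float:
    """Maximum angular displacement (degrees) of any visible dot in one frame.

    The protocol's upper velocity limit is set by how far individual dots
    jump between refreshes; this evaluates that jump by differencing the
    viewing directions of points visible both before and after one frame
    step (no wrapping, so the comparison tracks the same physical dots).
    """
    if geom.refresh <= 0:
        raise ValueError("refresh must be positive")
    dt = 1.0 / geom.refresh
    if motion.velocity == 0:
        proj = project_to_screen(field, geom)
        if proj.shape[0] == 0:
            raise ValueError("no visible points in the field")
        return 0.0
    after = propagate_starfield(field, motion, dt, wrap=False)
    vis0 = set(project_to_screen(field, geom)[:, 0].astype(int))
    vis1 = set(project_to_screen(after, geom)[:, 0].astype(int))
    common = sorted(vis0 & vis1)
    if not common:
        raise ValueError("no visible points in the field")
    p0 = field.points[common]
    p1 = after.points[common]
    u0 = p0 / np.linalg.norm(p0, axis=1, keepdims=True)
    u1 = p1 / np.linalg.norm(p1, axis=1, keepdims=True)
    cosang = np.clip(np.sum(u0 * u1, axis=1), -1.0, 1.0)
    return float(np.rad2deg(np.max(np.arccos(cosang))))


def grating_spec(
    wavelength: float,
    temporal_frequency: float = 5.0,
    contrast: float = 1.0,
    direction: float = 0.0,
    duration: float = 1.0,
    extent: str | float = "full",
) -> GratingSpec:
    """Build a grating specification; see :class:`GratingSpec`."""
    return GratingSpec(
        wavelength=wavelength,
        temporal_frequency=temporal_frequency,
        contrast=contrast,
        direction=direction,
        duration=duration,
        extent=extent,
    )
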