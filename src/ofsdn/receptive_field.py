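"""Receptive-field mapping and classification of optic-flow-sensitive
descending neurons (OFS DN1/DN2, left- and right-hand side).

The mapping protocol probes 48 overlapping ~38°x38° locations with local
gratings drifting in 8 directions.  Per location, the local maximum spike
frequency above spontaneous and a cosine fit (local preferred direction,
LPD; local motion sensitivity, LMS) are extracted.  The local-max lattice
is interpolated tenfold, the 50 %-of-maximum contour is traced and its
polygon gives the receptive-field centre, width and height.  The
receptive-field preferred direction is the circular median of LPDs at
locations whose LMS exceeds half the maximum; neurons with low LMS
(< 20 spikes/s), few supra-half locations (<= 4) or high LPD dispersion
(> 30°) are excluded, and the remainder classified by preferred
direction and centre azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon, box
from skimage import measure
from sklearn.cluster import KMeans

from .circstats import circ_dispersion, circ_median, fit_cosine

__all__ = [
    "NEURON_CLASSES",
    "EXCLUSION_DEFAULTS",
    "RFGrid",
    "LocalTuning",
    "ReceptiveFieldResult",
    "NeuronRecord",
    "local_tuning",
    "interpolate_map",
    "half_max_contour",
    "polygon_metrics",
    "rf_preferred_direction",
    "apply_exclusion",
    "classify_neuron",
    "transform_coordinates",
    "cluster_features",
    "map_receptive_field",
    "analyse_neuron",
]

NEURON_CLASSES = ("DN1_LHS", "DN1_RHS", "DN2_LHS", "DN2_RHS", "UNCLASSIFIED")

#: Exclusion thresholds: minimum maximal LMS (spikes/s), minimum number of
#: locations with LMS above half maximum, maximum LPD angular deviation (deg).
EXCLUSION_DEFAULTS = {"min_lms": 20.0, "min_positions": 5, "max_dispersion": 30.0}


@dataclass(frozen=True)
class RFGrid:
    """Mean per-direction spike rates on a regular lattice of patch centres.

    ``rates`` has shape (n_elevations, n_azimuths, n_directions), in
    spikes/s, not yet spontaneous-subtracted.
    """

    azimuths: np.ndarray
    elevations: np.ndarray
    directions: np.ndarray
    rates: np.ndarray
    spontaneous: float = 0.0

    def __post_init__(self):
        az = np.asarray(self.azimuths, dtype=float)
        el = np.asarray(self.elevations, dtype=float)
        di = np.asarray(self.directions, dtype=float)
        ra = np.asarray(self.rates, dtype=float)
        if ra.shape != (el.size, az.size, di.size):
            raise ValueError("rates must have shape (n_elevations, n_azimuths, n_directions)")
        for axis in (az, el):
            if axis.size > 1 and not np.allclose(np.diff(axis), axis[1] - axis[0]):
                raise ValueError("patch centres must form a regular lattice")
        object.__setattr__(self, "azimuths", az)
        object.__setattr__(self, "elevations", el)
        object.__setattr__(self, "directions", di)
        object.__setattr__(self, "rates", ra)

    @classmethod
    def from_table(cls, table: pd.DataFrame, spontaneous: float = 0.0) -> "RFGrid":
        """Build from a tidy response table with columns
        (location_azimuth, location_elevation, direction, repetition,
        spike_count, duration_s)."""
        required = {"location_azimuth", "location_elevation", "direction",
                    "spike_count", "duration_s"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"response table missing columns: {sorted(missing)}")
        df = table.copy()
        df["rate"] = df["spike_count"] / df["duration_s"]
        mean = (
            df.groupby(["location_elevation", "location_azimuth", "direction"])["rate"]
            .mean()
            .reset_index()
        )
        az = np.sort(mean["location_azimuth"].unique())
        el = np.sort(mean["location_elevation"].unique())
        di = np.sort(mean["direction"].unique())
        cube = (
            mean.pivot_table(
                index="location_elevation",
                columns=["location_azimuth", "direction"],
                values="rate",
            )
            .to_numpy()
            .reshape(el.size, az.size, di.size)
        )
        if np.any(np.isnan(cube)):
            raise ValueError("every location must have responses for every direction")
        return cls(azimuths=az, elevations=el, directions=di, rates=cube,
                   spontaneous=spontaneous)


@dataclass(frozen=True)
class LocalTuning:
    """Directional tuning at one patch: local max above spontaneous, LPD, LMS."""

    local_max: float
    lpd: float
    lms: float
    location: tuple[float, float]  # (azimuth, elevation) in degrees


@dataclass(frozen=True)
class ReceptiveFieldResult:
    dense_azimuths: np.ndarray
    dense_elevations: np.ndarray
    dense_map: np.ndarray
    contour: np.ndarray | None  # (N, 2) azimuth/elevation vertices, closed
    centre: tuple[float, float] | None
    width: float
    height: float
    preferred_direction: float
    lpd_dispersion: float
    n_over_half: int
    max_lms: float
    tunings: tuple
    border_clipped: bool = False


@dataclass(frozen=True)
class NeuronRecord:
    neuron_id: str
    neuron_class: str
    excluded: bool
    exclusion_reasons: tuple
    rf: ReceptiveFieldResult
    sex: str | None = None


def local_tuning(directions, mean_rates, spontaneous: float,
                 location=(0.0, 0.0)) -> LocalTuning:
    """Tuning at one location: local max above spontaneous plus cosine fit.

    The local maximum may be negative when every direction drives the
    neuron below its spontaneous rate; map construction floors it at 0.
    """
    di = np.asarray(directions, dtype=float)
    r = np.asarray(mean_rates, dtype=float)
    if di.size != r.size or di.size < 3:
        raise ValueError("need matching directions and rates for all directions")
    fit = fit_cosine(di, r)
    local_max = float(np.max(r) - spontaneous)
    return LocalTuning(local_max=local_max, lpd=fit.preferred_phase,
                       lms=fit.amplitude, location=tuple(map(float, location)))


def interpolate_map(azimuths, elevations, values, factor: int = 10,
                    kind: str = "linear") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate a lattice of local maxima to ``factor``-fold resolution.

    Bilinear by default (``kind='cubic'`` switches to a bicubic spline);
    values at the original nodes are preserved exactly in the linear case.
    Returns (dense_azimuths, dense_elevations, dense_values) with
    dense_values shaped (n_el_dense, n_az_dense).
    """
    az = np.asarray(azimuths, dtype=float)
    el = np.asarray(elevations, dtype=float)
    v = np.asarray(values, dtype=float)
    if v.shape != (el.size, az.size):
        raise ValueError("values must be shaped (n_elevations, n_azimuths)")
    if az.size < 2 or el.size < 2:
        raise ValueError("lattice must have at least two nodes per axis")
    for axis in (az, el):
        if not np.allclose(np.diff(axis), axis[1] - axis[0]):
            raise ValueError("patch centres must form a regular lattice")
    if factor < 1:
        raise ValueError("factor must be at least 1")
    az_d = np.linspace(az[0], az[-1], (az.size - 1) * factor + 1)
    el_d = np.linspace(el[0], el[-1], (el.size - 1) * factor + 1)
    if kind == "linear":
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((el, az), v, method="linear")
        grid_el, grid_az = np.meshgrid(el_d, az_d, indexing="ij")
        dense = interp(np.column_stack([grid_el.ravel(), grid_az.ravel()]))
        dense = dense.reshape(el_d.size, az_d.size)
    elif kind == "cubic":
        from scipy.interpolate import RectBivariateSpline

        kx = min(3, az.size - 1)
        ky = min(3, el.size - 1)
        spline = RectBivariateSpline(el, az, v, kx=ky, ky=kx)
        dense = spline(el_d, az_d)
    else:
        raise ValueError("kind must be 'linear' or 'cubic'")
    return az_d, el_d, dense


def half_max_contour(azimuths, elevations, dense_map,
                     level_fraction: float = 0.5) -> tuple[np.ndarray, bool]:
    """Iso-contour of the dense map at ``level_fraction`` of its maximum.

    Marching squares; among the closed contours, returns the one that
    encloses the map maximum (largest area if several do).  Contours
    clipped by the map border are closed along the border and flagged.
    Returns (closed polygon vertices (N, 2) as azimuth/elevation, flag).
    """
    az = np.asarray(azimuths, dtype=float)
    el = np.asarray(elevations, dtype=float)
    v = np.asarray(dense_map, dtype=float)
    vmax = float(np.nanmax(v))
    if vmax <= 0:
        raise ValueError("dense map must have a strictly positive maximum")
    level = level_fraction * vmax
    # Pad with a sub-level frame so every contour closes; portions outside
    # the original extent are then clipped back to the map border.
    pad_value = min(level - 1.0, float(np.nanmin(v)) - 1.0)
    padded = np.pad(v, 1, constant_values=pad_value)
    contours = measure.find_contours(padded, level)
    if not contours:
        raise ValueError("no contour found at the requested level")

    daz = az[1] - az[0]
    dele = el[1] - el[0]

    def to_world(c):
        # padded index (row, col) -> (azimuth, elevation)
        return np.column_stack([az[0] + (c[:, 1] - 1) * daz, el[0] + (c[:, 0] - 1) * dele])

    imax = np.unravel_index(np.nanargmax(v), v.shape)
    peak = Point(az[imax[1]], el[imax[0]])
    bbox = box(az[0], el[0], az[-1], el[-1])

    candidates = []
    for c in contours:
        world = to_world(c)
        poly = Polygon(world)
        if not poly.is_valid:
            poly = poly.buffer(0)
        clipped = poly.intersection(bbox)
        was_clipped = not np.isclose(clipped.area, poly.area, rtol=1e-9, atol=1e-12)
        geoms = clipped.geoms if isinstance(clipped, MultiPolygon) else [clipped]
        for g in geoms:
            if g.is_empty or g.area == 0:
                continue
            candidates.append((g, was_clipped))
    if not candidates:
        raise ValueError("no usable contour polygon at the requested level")
    enclosing = [(g, f) for g, f in candidates if g.contains(peak) or g.touches(peak)]
    pool = enclosing if enclosing else candidates
    poly, clipped_flag = max(pool, key=lambda gf: gf[0].area)
    coords = np.asarray(poly.exterior.coords)
    return coords, bool(clipped_flag)


def polygon_metrics(polygon) -> tuple[float, float, tuple[float, float]]:
    """Width (azimuth extent), height (elevation extent) and area centroid.

    Accepts a shapely polygon or an (N, 2) vertex array; the polygon must
    be simple (non-self-intersecting).
    """
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon, float))
    if not poly.is_valid or poly.area == 0:
        raise ValueError("polygon must be simple (non-self-intersecting) with area")
    x0, y0, x1, y1 = poly.bounds
    c = poly.centroid
    return float(x1 - x0), float(y1 - y0), (float(c.x), float(c.y))


def rf_preferred_direction(tunings) -> tuple[float, float, int]:
    """Receptive-field preferred direction from local tunings.

    Selects locations whose LMS exceeds half the maximum LMS (the
    maximal location always qualifies), takes the circular median of
    their LPDs, and reports the angular deviation of the same set and
    the number of selected locations.
    """
    tunings = list(tunings)
    if not tunings:
        raise ValueError("at least one local tuning required")
    lms = np.array([t.lms for t in tunings], dtype=float)
    lpd = np.array([t.lpd for t in tunings], dtype=float)
    max_lms = float(np.max(lms))
    if max_lms <= 0:
        return float("nan"), float("nan"), 0
    sel = (lms > 0.5 * max_lms) & np.isfinite(lpd)
    chosen = lpd[sel]
    if chosen.size == 0:
        return float("nan"), float("nan"), 0
    pd_ = circ_median(chosen)
    disp = circ_dispersion(chosen).angular_deviation if chosen.size >= 2 else 0.0
    return float(pd_), float(disp), int(chosen.size)


def apply_exclusion(
    max_lms: float,
    n_over_half: int,
    lpd_dispersion: float,
    min_lms: float = EXCLUSION_DEFAULTS["min_lms"],
    min_positions: int = EXCLUSION_DEFAULTS["min_positions"],
    max_dispersion: float = EXCLUSION_DEFAULTS["max_dispersion"],
) -> tuple[bool, tuple]:
    """Exclusion rule: low LMS, too few supra-half locations, or high LPD spread.

    Excluded iff max LMS < 20 spikes/s OR the number of locations with LMS
    above half maximum is 4 or fewer OR the LPD angular deviation exceeds
    30°.  Every failed criterion is reported.
    """
    reasons = []
    if max_lms < min_lms:
        reasons.append("low_lms")
    if n_over_half < min_positions:
        reasons.append("few_positions")
    if np.isfinite(lpd_dispersion) and lpd_dispersion > max_dispersion:
        reasons.append("high_lpd_dispersion")
    if not np.isfinite(lpd_dispersion):
        reasons.append("undefined_preferred_direction")
    return bool(reasons), tuple(reasons)


def classify_neuron(preferred_direction: float, centre_azimuth: float) -> str:
    """Classify by preferred direction and receptive-field centre azimuth.

    DN1_LHS for directions in [120°, 200°]; DN1_RHS in [340°, 60°]
    (wrapping through 0); DN2 in [220°, 320°] with the sign of the centre
    azimuth choosing the side (negative = left of midline).  Boundary
    angles are classified inclusively; anything else is UNCLASSIFIED.
    """
    if not np.isfinite(preferred_direction):
        return "UNCLASSIFIED"
    d = float(np.mod(preferred_direction, 360.0))
    if 120.0 <= d <= 200.0:
        return "DN1_LHS"
    if d >= 340.0 or d <= 60.0:
        return "DN1_RHS"
    if 220.0 <= d <= 320.0:
        return "DN2_LHS" if centre_azimuth < 0 else "DN2_RHS"
    return "UNCLASSIFIED"


def _transform_direction(theta: float, ventral_up: bool, mirror: bool) -> float:
    if not np.isfinite(theta):
        return theta
    out = theta
    if ventral_up:
        out = (out + 180.0) % 360.0
    if mirror:
        out = (180.0 - out) % 360.0
    return float(out)


def transform_coordinates(
    rf: ReceptiveFieldResult, ventral_up: bool = False, mirror_to_rhs: bool = False
) -> ReceptiveFieldResult:
    """Display transforms of a mapped receptive field.

    ``ventral_up`` undoes the ventral-side-up recording position: all
    directions rotate by 180° and both map axes are negated.
    ``mirror_to_rhs`` flips a left-side neuron across the midline:
    azimuths are negated and directions map theta -> (180° - theta).
    Each transform is an involution; LMS values and the supra-half count
    are untouched.
    """
    az = rf.dense_azimuths.copy()
    el = rf.dense_elevations.copy()
    dense = rf.dense_map.copy()
    contour = None if rf.contour is None else rf.contour.copy()
    centre = rf.centre

    def flip_az():
        nonlocal az, dense, contour, centre
        az = -az[::-1]
        dense = dense[:, ::-1]
        if contour is not None:
            contour = np.column_stack([-contour[:, 0], contour[:, 1]])
        if centre is not None:
            centre = (-centre[0], centre[1])

    def flip_el():
        nonlocal el, dense, contour, centre
        el = -el[::-1]
        dense = dense[::-1, :]
        if contour is not None:
            contour = np.column_stack([contour[:, 0], -contour[:, 1]])
        if centre is not None:
            centre = (centre[0], -centre[1])

    def tune_loc(t: LocalTuning, negate_az: bool, negate_el: bool) -> tuple[float, float]:
        a, e = t.location
        return (-a if negate_az else a, -e if negate_el else e)

    if ventral_up:
        flip_az()
        flip_el()
    if mirror_to_rhs:
        flip_az()

    tunings = tuple(
        replace(
            t,
            lpd=_transform_direction(t.lpd, ventral_up, mirror_to_rhs),
            location=tune_loc(t, ventral_up != mirror_to_rhs, ventral_up),
        )
        for t in rf.tunings
    )
    return replace(
        rf,
        dense_azimuths=az,
        dense_elevations=el,
        dense_map=dense,
        contour=contour,
        centre=centre,
        preferred_direction=_transform_direction(
            rf.preferred_direction, ventral_up, mirror_to_rhs
        ),
        tunings=tunings,
    )


def cluster_features(features, k: int, seed: int | None = None,
                     n_restarts: int = 50) -> tuple[np.ndarray, float]:
    """k-means on z-scored features plus the Calinski-Harabasz index.

    The index is computed from its definition,
    CH = (trace(B)/(k-1)) / (trace(W)/(n-k)), with B and W the between-
    and within-cluster dispersion about the grand and cluster centroids.
    Note the preferred direction enters as a plain linear feature; the
    circular wrap is not special-cased (documented caveat).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError("k cannot exceed the number of observations")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z)
    grand = z.mean(axis=0)
    between = 0.0
    within = 0.0
    for j in range(k):
        members = z[labels == j]
        cj = members.mean(axis=0)
        between += members.shape[0] * float(np.sum((cj - grand) ** 2))
        within += float(np.sum((members - cj) ** 2))
    if within <= 0:
        ch = float("inf")
    else:
        ch = (between / (k - 1)) / (within / (n - k))
    return labels, float(ch)


def map_receptive_field(grid: RFGrid, interpolation: str = "linear",
                        factor: int = 10) -> ReceptiveFieldResult:
    """Full receptive-field pipeline on one neuron's mapping grid.

    Local maxima below spontaneous are floored at 0 before interpolation
    and contouring (suppression cannot contribute receptive-field area).
    A map with no positive response yields NaN geometry; the neuron will
    then fail the low-LMS exclusion criterion downstream.
    """
    tunings = []
    local_max = np.zeros((grid.elevations.size, grid.azimuths.size))
    for i, e in enumerate(grid.elevations):
        for j, a in enumerate(grid.azimuths):
            t = local_tuning(grid.directions, grid.rates[i, j, :],
                             grid.spontaneous, location=(a, e))
            tunings.append(t)
            local_max[i, j] = max(t.local_max, 0.0)
    az_d, el_d, dense = interpolate_map(grid.azimuths, grid.elevations,
                                        local_max, factor=factor, kind=interpolation)
    pd_, disp, n_half = rf_preferred_direction(tunings)
    max_lms = float(max((t.lms for t in tunings), default=0.0))
    if np.nanmax(dense) > 0:
        contour, clipped = half_max_contour(az_d, el_d, dense)
        width, height, centre = polygon_metrics(contour)
    else:
        contour, clipped = None, False
        width = height = float("nan")
        centre = None
    return ReceptiveFieldResult(
        dense_azimuths=az_d,
        dense_elevations=el_d,
        dense_map=dense,
        contour=contour,
        centre=centre,
        width=width,
        height=height,
        preferred_direction=pd_,
        lpd_dispersion=disp,
        n_over_half=n_half,
        max_lms=max_lms,
        tunings=tuple(tunings),
        border_clipped=clipped,
    )


def analyse_neuron(grid: RFGrid, neuron_id: str = "", sex: str | None = None,
                   ventral_up: bool = False, **exclusion_kwargs) -> NeuronRecord:
    """Map, exclude and classify one neuron; class assigned only if retained."""
    rf = map_receptive_field(grid)
    if ventral_up:
        rf = transform_coordinates(rf, ventral_up=True)
    excluded, reasons = apply_exclusion(
        rf.max_lms, rf.n_over_half, rf.lpd_dispersion, **exclusion_kwargs
    )
    if excluded or rf.centre is None:
        cls = "UNCLASSIFIED"
        if not excluded:
            excluded, reasons = True, ("no_contour",)
    else:
        cls = classify_neuron(rf.preferred_direction, rf.centre[0])
    return NeuronRecord(
        neuron_id=neuron_id,
        neuron_class=cls,
        excluded=excluded,
        exclusion_reasons=reasons,
        rf=rf,
        sex=sex,
    )
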