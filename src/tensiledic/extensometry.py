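"""Virtual extensometers, dynamic Poisson's ratio and force synchronization.

A virtual extensometer measures the distance between two tracked anchor
point sets in the image, replacing a physical gauge. Three are placed by
default: one spanning the gauge section along the loading axis, one spanning
a short zone around the crack (3 mm by default), and one spanning the
specimen width at mid-gauge. The axial and transverse distance series
combine into an instantaneous (dynamic) Poisson's ratio
nu(t) = -ln(w(t)/w0) / ln(h(t)/h0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dic import DisplacementFieldSeries, SubsetGrid
from .errors import InvalidArgumentError, MeasurementGapError
from .geometry import ForceTrace, SpecimenGeometry

__all__ = [
    "VirtualExtensometer",
    "DistanceSeries",
    "PoissonTrajectory",
    "place_extensometers",
    "measure_distance",
    "poisson_trajectory",
    "synchronize",
    "detect_crack_line",
]

AXIAL_STRAIN_FLOOR = 0.005  # below this the strain ratio is a 0/0
POISSON_SANITY_BAND = (-0.1, 0.6)


@dataclass(frozen=True)
class VirtualExtensometer:
    """Two anchor point sets in reference-image coordinates.

    ``role`` is 'gauge' or 'crack' (axial, distance measured along y) or
    'transverse' (distance along x). Each anchor is a set of (y, x) points
    whose displacements are averaged; the sets are symmetric about the
    anchor location along the perpendicular axis so the averaging does not
    bias the measured axis.
    """

    points_a: np.ndarray  # (m, 2) as (y, x) px
    points_b: np.ndarray
    role: str
    nominal_length_mm: float

    def __post_init__(self) -> None:
        if self.role not in ("gauge", "crack", "transverse"):
            raise InvalidArgumentError("role must be gauge, crack or transverse")
        if self.nominal_length_mm <= 0:
            raise InvalidArgumentError("nominal length must be positive")

    @property
    def axis(self) -> int:
        """Displacement component index measured: 0 = u (x), 1 = v (y)."""
        return 0 if self.role == "transverse" else 1


@dataclass
class DistanceSeries:
    """Distance (mm) per frame from one source.

    ``source`` is 'texture_analyser', 'dic_gauge', 'dic_crack' or
    'dic_transverse'. Frames where an anchor could not be interpolated carry
    NaN (a measurement gap).
    """

    times: np.ndarray
    distance_mm: np.ndarray
    source: str
    nominal_length_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        if len(self.times) != len(self.distance_mm):
            raise InvalidArgumentError("times and distances must align")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")


@dataclass
class PoissonTrajectory:
    """Instantaneous Poisson's ratio against axial true strain.

    Only frames whose axial strain exceeds the configured floor are kept.
    ``flagged`` marks ratios outside the physical sanity band.
    """

    times: np.ndarray
    axial_true_strain: np.ndarray
    ratio: np.ndarray
    width_mm: np.ndarray
    flagged: np.ndarray
    strain_floor: float


def _hull(grid: SubsetGrid) -> tuple[float, float, float, float]:
    ys = grid.centers[:, 0]
    xs = grid.centers[:, 1]
    return ys.min(), ys.max(), xs.min(), xs.max()


def _anchor_set(y: float, x: float, role: str, spread_px: float) -> np.ndarray:
    """Three points symmetric about the anchor along the perpendicular axis."""
    if role == "transverse":
        pts = [(y - spread_px, x), (y, x), (y + spread_px, x)]
    else:
        pts = [(y, x - spread_px), (y, x), (y, x + spread_px)]
    return np.asarray(pts, dtype=float)


def place_extensometers(
    grid: SubsetGrid,
    geometry: SpecimenGeometry,
    pixel_scale: float,
    crack_zone_length_mm: float = 3.0,
    crack_position_px: float | None = None,
    specimen_center_px: tuple[float, float] | None = None,
) -> list[VirtualExtensometer]:
    """Gauge, crack-zone and transverse extensometers for one specimen.

    The gauge extensometer spans h0 along the loading axis; the crack
    extensometer spans ``crack_zone_length_mm`` centred on the crack line
    (mid-gauge when not given); the transverse extensometer spans the initial
    specimen width at mid-gauge. All anchors must land inside the subset
    grid's convex hull.
    """
    if pixel_scale <= 0 or crack_zone_length_mm <= 0:
        raise InvalidArgumentError("pixel_scale and crack zone length must be positive")
    h, w = grid.image_shape
    if specimen_center_px is None:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        cy, cx = specimen_center_px
    y_min, y_max, x_min, x_max = _hull(grid)
    spread = float(grid.step)

    half_gauge_px = geometry.gauge_length_mm / 2.0 / pixel_scale
    g_a, g_b = cy - half_gauge_px, cy + half_gauge_px
    if g_a < y_min - grid.step or g_b > y_max + grid.step:
        raise InvalidArgumentError("gauge section extends outside the tracked region")

    crack_y = cy if crack_position_px is None else float(crack_position_px)
    half_crack_px = crack_zone_length_mm / 2.0 / pixel_scale
    c_a, c_b = crack_y - half_crack_px, crack_y + half_crack_px

    half_width_px = geometry.width0_mm / 2.0 / pixel_scale
    t_a, t_b = cx - half_width_px, cx + half_width_px
    if t_a < x_min - grid.step or t_b > x_max + grid.step:
        raise InvalidArgumentError("specimen width extends outside the tracked region")

    return [
        VirtualExtensometer(
            points_a=_anchor_set(g_a, cx, "gauge", spread),
            points_b=_anchor_set(g_b, cx, "gauge", spread),
            role="gauge",
            nominal_length_mm=geometry.gauge_length_mm,
        ),
        VirtualExtensometer(
            points_a=_anchor_set(c_a, cx, "crack", spread),
            points_b=_anchor_set(c_b, cx, "crack", spread),
            role="crack",
            nominal_length_mm=crack_zone_length_mm,
        ),
        VirtualExtensometer(
            points_a=_anchor_set(cy, t_a, "transverse", spread),
            points_b=_anchor_set(cy, t_b, "transverse", spread),
            role="transverse",
            nominal_length_mm=geometry.width0_mm,
        ),
    ]


def _interp_displacement(
    fields: DisplacementFieldSeries, frame: int, point: np.ndarray, axis: int, idw_radius: float
) -> float:
    """Displacement component at an arbitrary point from the subset lattice.

    Bilinear interpolation over the enclosing lattice cell when all four
    corners are valid; otherwise inverse-distance weighting over the valid
    subsets within ``idw_radius``. Raises MeasurementGapError when no valid
    subset is near.
    """
    grid = fields.grid
    rows, cols = grid.grid_shape
    comp = (fields.u if axis == 0 else fields.v)[frame].reshape(rows, cols)
    ok = fields.valid[frame].reshape(rows, cols)
    y0 = grid.centers[0, 0]
    x0 = grid.centers[0, 1]
    fy = (point[0] - y0) / grid.step
    fx = (point[1] - x0) / grid.step
    iy = int(np.floor(fy))
    ix = int(np.floor(fx))
    if 0 <= iy and iy + 1 < rows and 0 <= ix and ix + 1 < cols:
        cell_ok = ok[iy : iy + 2, ix : ix + 2]
        if cell_ok.all():
            wy, wx = fy - iy, fx - ix
            c = comp[iy : iy + 2, ix : ix + 2]
            return float(
                c[0, 0] * (1 - wy) * (1 - wx)
                + c[0, 1] * (1 - wy) * wx
                + c[1, 0] * wy * (1 - wx)
                + c[1, 1] * wy * wx
            )
    # fallback: inverse-distance weighting over nearby valid subsets
    d = np.hypot(
        grid.centers[:, 0] - point[0], grid.centers[:, 1] - point[1]
    )
    near = (d <= idw_radius) & fields.valid[frame]
    if not near.any():
        raise MeasurementGapError(f"no valid subset within {idw_radius:.1f} px of anchor")
    dd = np.maximum(d[near], 1e-6)
    wgt = 1.0 / dd
    vals = (fields.u if axis == 0 else fields.v)[frame][near]
    return float((wgt * vals).sum() / wgt.sum())


def measure_distance(
    ext: VirtualExtensometer,
    fields: DisplacementFieldSeries,
    pixel_scale: float,
    idw_radius_factor: float = 1.5,
) -> DistanceSeries:
    """Distance between the two anchor sets at every frame, in mm.

    Each anchor's displacement along the measured axis is the mean over its
    point set of the interpolated subset displacement; the series is the
    nominal length plus the relative displacement. Frames where an anchor
    cannot be interpolated carry NaN.
    """
    if pixel_scale <= 0:
        raise InvalidArgumentError("pixel_scale must be positive")
    idw_radius = idw_radius_factor * fields.grid.step
    axis = ext.axis
    n = fields.n_frames
    dist = np.empty(n)
    gaps = 0
    for f in range(n):
        try:
            da = np.mean([
                _interp_displacement(fields, f, p, axis, idw_radius) for p in ext.points_a
            ])
            db = np.mean([
                _interp_displacement(fields, f, p, axis, idw_radius) for p in ext.points_b
            ])
            dist[f] = ext.nominal_length_mm + (db - da) * pixel_scale
        except MeasurementGapError:
            dist[f] = np.nan
            gaps += 1
    return DistanceSeries(
        times=fields.frame_times,
        distance_mm=dist,
        source=f"dic_{ext.role}",
        nominal_length_mm=ext.nominal_length_mm,
        meta={"gaps": gaps, "idw_radius_px": idw_radius},
    )


def poisson_trajectory(
    axial: DistanceSeries,
    transverse: DistanceSeries,
    strain_floor: float = AXIAL_STRAIN_FLOOR,
) -> PoissonTrajectory:
    """Dynamic Poisson's ratio from axial and transverse distance series.

    nu(t) = -ln(w(t)/w0) / ln(h(t)/h0) with true (logarithmic) strains in
    both axes. Frames below the axial-strain floor are omitted (the ratio is
    a 0/0 there); ratios outside the sanity band are kept but flagged.
    """
    if len(axial.times) != len(transverse.times) or not np.allclose(
        axial.times, transverse.times
    ):
        raise InvalidArgumentError("axial and transverse series must share a time base")
    h = axial.distance_mm
    w = transverse.distance_mm
    if np.any(h[np.isfinite(h)] <= 0) or np.any(w[np.isfinite(w)] <= 0):
        raise InvalidArgumentError("distances must be positive")
    eps_a = np.log(h / axial.nominal_length_mm)
    eps_t = np.log(w / transverse.nominal_length_mm)
    keep = np.isfinite(eps_a) & np.isfinite(eps_t) & (eps_a > strain_floor)
    ratio = -eps_t[keep] / eps_a[keep]
    lo, hi = POISSON_SANITY_BAND
    return PoissonTrajectory(
        times=axial.times[keep],
        axial_true_strain=eps_a[keep],
        ratio=ratio,
        width_mm=w[keep],
        flagged=(ratio < lo) | (ratio > hi),
        strain_floor=strain_floor,
    )


def detect_crack_line(strain, grid: SubsetGrid) -> float:
    """y position (px) of the row with the largest mean axial strain.

    A convenience for centring the crack-zone extensometer on a transverse
    crack: the row of the subset lattice whose valid-subset mean eps_yy is
    largest. This is a band argmax, not crack-path tracing.
    """
    rows, cols = grid.grid_shape
    eyy = np.where(strain.valid, strain.eyy, np.nan).reshape(rows, cols)
    row_mean = np.nanmean(eyy, axis=1)
    if np.all(np.isnan(row_mean)):
        raise InvalidArgumentError("no valid strain values to locate a crack")
    best = int(np.nanargmax(row_mean))
    return float(grid.centers.reshape(rows, cols, 2)[best, 0, 0])


def synchronize(
    frame_times: np.ndarray,
    force: ForceTrace,
    dic_distances: dict[str, DistanceSeries] | None = None,
    time_offset_s: float = 0.0,
) -> pd.DataFrame:
    """Align the force trace (and DIC distance series) onto the frame clock.

    Force and machine distance are linearly interpolated at
    ``frame_time + time_offset_s`` (the camera-trigger lag between the two
    clocks). Frames outside the overlap of the two spans are dropped; fully
    disjoint spans are an error.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    shifted = frame_times + time_offset_s
    t0, t1 = force.time_s[0], force.time_s[-1]
    inside = (shifted >= t0 - 1e-9) & (shifted <= t1 + 1e-9)
    if not inside.any():
        raise InvalidArgumentError("frame times and force trace do not overlap")
    out = pd.DataFrame(
        {
            "time_s": frame_times[inside],
            "force_n": np.interp(shifted[inside], force.time_s, force.force_n),
            "machine_distance_mm": np.interp(
                shifted[inside], force.time_s, force.distance_mm
            ),
        }
    )
    for name, series in (dic_distances or {}).items():
        if len(series.times) == len(frame_times) and np.allclose(series.times, frame_times):
            out[name] = series.distance_mm[inside]
        else:
            out[name] = np.interp(
                frame_times[inside], series.times, series.distance_mm
            )
    return out
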