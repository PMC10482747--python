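"""True stress-strain curves and tensile parameter extraction.

True stress is force over the instantaneous cross-section, sigma(t) =
F(t)/A(t); true strain is the logarithm of the instantaneous over the
initial gauge length, eps(t) = ln(h(t)/h0). Two cross-section models are
supported: the constant-volume model A(t) = h0/h(t) A0 (incompressibility,
nu = 0.5) and the DIC-corrected dynamic-Poisson model A(t) =
width_DIC(t) (width_DIC(t)/width0) thickness0, which assumes the thickness
shrinks by the same fraction as the measured width. From a curve the module
extracts the fracture point (the last stress maximum before a sharp drop),
the Young's modulus (slope of the best linear window), the toughness (area
under the curve), and direction-paired anisotropy indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, NoFractureError
from .geometry import SpecimenGeometry

__all__ = [
    "StressStrainCurve",
    "TensileParameters",
    "AnisotropyIndices",
    "area_constant_volume",
    "area_dynamic_poisson",
    "true_stress",
    "true_strain",
    "detect_fracture",
    "youngs_modulus",
    "toughness",
    "anisotropy_index",
    "deformation_rate_for_gap",
    "extract_parameters",
]


@dataclass
class StressStrainCurve:
    """sigma(t)-eps(t) pairs tagged with their provenance.

    ``area_model`` is 'constant_volume' or 'dynamic_poisson';
    ``length_source`` records which distance fed the strain ('machine',
    'dic_gauge' or 'dic_crack').
    """

    strain: np.ndarray
    stress_pa: np.ndarray
    area_model: str
    length_source: str
    geometry: SpecimenGeometry | None = None
    times: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_pa = np.asarray(self.stress_pa, dtype=float)
        if len(self.strain) != len(self.stress_pa):
            raise InvalidArgumentError("strain and stress must align")
        if self.area_model not in ("constant_volume", "dynamic_poisson"):
            raise InvalidArgumentError(f"unknown area model {self.area_model!r}")

    def __len__(self) -> int:
        return len(self.strain)


@dataclass
class TensileParameters:
    """Scalar parameters extracted from one stress-strain curve."""

    fracture_stress_pa: float
    fracture_strain: float
    youngs_modulus_pa: float
    toughness_pa: float  # J/m^3, numerically Pa
    toughness_full_curve_pa: float
    fracture_index: int
    linear_window: tuple[float, float]  # strain interval used for the modulus
    modulus_r2: float
    modulus_below_floor: bool


@dataclass(frozen=True)
class AnisotropyIndices:
    """Parallel/perpendicular ratios of the main tensile parameters."""

    fracture_stress: float
    youngs_modulus: float
    toughness: float


def area_constant_volume(h0_mm: float, h_t_mm, a0_mm2: float):
    """Instantaneous area under incompressibility: A(t) = h0/h(t) A0."""
    h_t = np.asarray(h_t_mm, dtype=float)
    if h0_mm <= 0 or a0_mm2 <= 0 or np.any(h_t <= 0):
        raise InvalidArgumentError("lengths and area must be positive")
    return h0_mm / h_t * a0_mm2


def area_dynamic_poisson(width_dic_mm, width0_mm: float, thickness0_mm: float):
    """DIC-corrected area: A(t) = w_DIC(t) (w_DIC(t)/w0) t0.

    The unobserved thickness is assumed to shrink by the same fraction as
    the measured width. Widths exceeding the initial width (possible with
    measurement noise) are passed through unchanged.
    """
    w = np.asarray(width_dic_mm, dtype=float)
    if width0_mm <= 0 or thickness0_mm <= 0 or np.any(w <= 0):
        raise InvalidArgumentError("widths and thickness must be positive")
    return w * (w / width0_mm) * thickness0_mm


def true_stress(force_n, area_m2):
    """Elementwise sigma = F/A in Pa (force in N, area in m^2)."""
    f = np.asarray(force_n, dtype=float)
    a = np.asarray(area_m2, dtype=float)
    if f.shape != a.shape:
        raise InvalidArgumentError("force and area series must align")
    if np.any(a <= 0):
        raise InvalidArgumentError("areas must be positive")
    return f / a


def true_strain(h0_mm: float, h_series_mm):
    """Elementwise logarithmic strain ln(h/h0)."""
    h = np.asarray(h_series_mm, dtype=float)
    if h0_mm <= 0 or np.any(h <= 0):
        raise InvalidArgumentError("lengths must be positive")
    return np.log(h / h0_mm)


def detect_fracture(
    curve: StressStrainCurve, drop_fraction: float = 0.3, window: int | None = None
) -> int:
    """Index of the fracture point: the last stress maximum before the first
    sharp drop.

    A drop qualifies when stress falls by at least ``drop_fraction`` of the
    running peak within ``window`` samples (default 2% of the curve, minimum
    3). Raises :class:`NoFractureError` when the curve ends without one.
    """
    s = curve.stress_pa
    n = len(s)
    if window is None:
        window = max(3, int(round(0.02 * n)))
    if n < window + 2:
        raise InvalidArgumentError("curve too short for the drop window")
    run_peak = np.maximum.accumulate(s)
    for i in range(n - 1):
        j = min(i + window, n - 1)
        seg = s[i : j + 1]
        m = int(np.argmax(seg))
        drop = seg[m] - seg[m:].min()  # decline after the window's maximum
        if run_peak[j] > 0 and drop >= drop_fraction * run_peak[j]:
            # that maximum, extended back through any plateau, is the
            # fracture point
            k = i + m
            while k > 0 and s[k - 1] >= s[k]:
                k -= 1
            return k
    raise NoFractureError("no qualifying stress drop before the end of the curve")


def youngs_modulus(
    curve: StressStrainCurve,
    min_span_strain: float = 0.02,
    r2_floor: float = 0.99,
    fracture_index: int | None = None,
) -> tuple[float, tuple[float, float], float, bool]:
    """Slope of the best linear pre-fracture window of the stress-strain curve.

    Scans every contiguous window whose strain span is at least
    ``min_span_strain`` (each start index paired with the smallest end
    reaching the span), and returns
    the slope of the window with the highest coefficient of determination,
    ties broken toward the earliest window. If no window reaches
    ``r2_floor`` the best window is still returned, with a below-floor flag.

    Returns (modulus_pa, (strain_lo, strain_hi), r2, below_floor).
    """
    eps = curve.strain
    sig = curve.stress_pa
    end = fracture_index + 1 if fracture_index is not None else len(eps)
    eps, sig = eps[:end], sig[:end]
    n = len(eps)
    if n < 3 or eps[-1] - eps[0] < min_span_strain:
        raise InvalidArgumentError("pre-fracture segment shorter than the minimum span")

    # prefix sums for O(1) regression statistics on any window
    cs = np.concatenate([[0.0], np.cumsum(eps)])
    cs2 = np.concatenate([[0.0], np.cumsum(eps * eps)])
    cy = np.concatenate([[0.0], np.cumsum(sig)])
    cy2 = np.concatenate([[0.0], np.cumsum(sig * sig)])
    cxy = np.concatenate([[0.0], np.cumsum(eps * sig)])

    def fit(i: int, j: int) -> tuple[float, float]:
        """slope, r2 over samples [i, j]."""
        m = j - i + 1
        sx = cs[j + 1] - cs[i]
        sxx = cs2[j + 1] - cs2[i]
        sy = cy[j + 1] - cy[i]
        syy = cy2[j + 1] - cy2[i]
        sxy = cxy[j + 1] - cxy[i]
        vx = sxx - sx * sx / m
        vy = syy - sy * sy / m
        cov = sxy - sx * sy / m
        if vx <= 0:
            return 0.0, -np.inf
        slope = cov / vx
        if vy <= 0:
            return slope, 1.0  # flat stress: degenerate but perfectly "fit"
        r2 = cov * cov / (vx * vy)
        return slope, r2

    best = None  # (r2, start, slope, (lo, hi))
    ends = np.searchsorted(eps, eps + min_span_strain)
    for i in range(n):
        j = int(ends[i])
        if j >= n:
            break
        slope, r2 = fit(i, j)
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, i, slope, (float(eps[i]), float(eps[j])))
    if best is None:
        raise InvalidArgumentError("no window spans the minimum strain")
    r2, _, slope, win = best
    return float(slope), win, float(r2), bool(r2 < r2_floor)


def toughness(
    curve: StressStrainCurve,
    fracture_index: int | None = None,
    include_descending: bool = False,
) -> float:
    """Area under the stress-strain curve (trapezoidal), in Pa = J/m^3.

    Integrates to the fracture point by default; ``include_descending=True``
    integrates the full recorded curve. The to-fracture default still
    overestimates the work of fracture for brittle products when crack
    propagation outruns the crosshead, so both variants are usually reported
    side by side.
    """
    eps = curve.strain
    sig = curve.stress_pa
    if np.any(np.diff(eps) < 0):
        raise InvalidArgumentError("strain must be non-decreasing for integration")
    if include_descending or fracture_index is None:
        return float(np.trapezoid(sig, eps))
    if not (0 <= fracture_index < len(eps)):
        raise InvalidArgumentError("fracture index outside the curve")
    return float(np.trapezoid(sig[: fracture_index + 1], eps[: fracture_index + 1]))


def anisotropy_index(param_parallel: float, param_perpendicular: float) -> float:
    """Ratio of a tensile parameter parallel over perpendicular to shear flow."""
    if param_perpendicular <= 0 or param_parallel <= 0:
        raise InvalidArgumentError("anisotropy index needs positive parameters")
    return param_parallel / param_perpendicular


def deformation_rate_for_gap(
    gap_width_mm: float,
    reference_rate_mm_per_min: float = 60.0,
    reference_gap_mm: float = 26.0,
) -> float:
    """Deformation rate keeping the nominal strain rate constant across moulds.

    Grip-to-grip gap widths differ between mould sizes; holding
    rate/gap constant (the reference mould pulls 60.0 mm/min over a 26.0 mm
    gap) gives every specimen the same nominal engineering strain rate.
    """
    if gap_width_mm <= 0 or reference_rate_mm_per_min <= 0 or reference_gap_mm <= 0:
        raise InvalidArgumentError("gaps and rates must be positive")
    return reference_rate_mm_per_min / reference_gap_mm * gap_width_mm


def extract_parameters(
    curve: StressStrainCurve,
    drop_fraction: float = 0.3,
    drop_window: int | None = None,
    min_span_strain: float = 0.02,
    r2_floor: float = 0.99,
) -> TensileParameters:
    """Fracture point, modulus and toughness of one curve in a single pass."""
    fi = detect_fracture(curve, drop_fraction=drop_fraction, window=drop_window)
    e_mod, win, r2, below = youngs_modulus(
        curve, min_span_strain=min_span_strain, r2_floor=r2_floor, fracture_index=fi
    )
    return TensileParameters(
        fracture_stress_pa=float(curve.stress_pa[fi]),
        fracture_strain=float(curve.strain[fi]),
        youngs_modulus_pa=e_mod,
        toughness_pa=toughness(curve, fracture_index=fi),
        toughness_full_curve_pa=toughness(curve, include_descending=True),
        fracture_index=fi,
        linear_window=win,
        modulus_r2=r2,
        modulus_below_floor=below,
    )
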