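"""Ground-truthed synthetic tensile specimens.

Generates speckle-image sequences warped by a prescribed deformation field
(axial stretch, Poisson-controlled lateral contraction, optional crack
opening) together with matching texture-analyser force traces, so that the
DIC engine, extensometry and metrics stages can be validated against known
answers without any experimental data.

Conventions: image origin top-left, x rightward (axis 1), y downward
(axis 0); the loading axis is y. Deformation is centred on the image centre.
The frame at t = 0 is always the undeformed reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, OutOfRangeError
from .geometry import ForceTrace, SpecimenGeometry

__all__ = [
    "SpecklePattern",
    "CrackSchedule",
    "DeformationSchedule",
    "MaterialArchetype",
    "ImageSequence",
    "gen_speckle",
    "warp_frame",
    "displacement_field",
    "render_sequence",
    "gen_force_trace",
]

# Rendered intensities: white acrylic background with dark spray-paint dots.
BACKGROUND_INTENSITY = 230.0
DOT_INTENSITY = 25.0
CRACK_FILL_INTENSITY = 12.0


@dataclass(frozen=True)
class SpecklePattern:
    """A speckle raster: randomly placed anti-aliased dark dots on a light field."""

    image: np.ndarray  # uint8, shape (H, W)
    pixel_scale: float  # mm per pixel
    dot_density: float  # expected dots per px^2
    dot_radius_range: tuple[float, float]  # px
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class CrackSchedule:
    """A single straight crack line transverse to loading.

    The two sides separate rigidly: material below the line (larger y)
    translates by the opening displacement. ``position_mm`` locates the line
    relative to the gauge centre along the loading axis.
    """

    onset_s: float
    position_mm: float
    opening_mm: np.ndarray  # aligned with DeformationSchedule.times

    def __post_init__(self) -> None:
        object.__setattr__(self, "opening_mm", np.asarray(self.opening_mm, dtype=float))


@dataclass(frozen=True)
class DeformationSchedule:
    """Prescribed axial stretch and Poisson-ratio trajectory over time.

    ``axial_stretch`` is the stretch ratio lambda(t) = h(t)/h0 >= 1 with
    lambda(0) = 1; the transverse stretch follows lambda**(-nu), the
    true-strain-consistent contraction, so nu = -eps_transverse/eps_axial
    holds exactly in the generated field.
    """

    times: np.ndarray
    axial_stretch: np.ndarray
    poisson: np.ndarray
    crack: CrackSchedule | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "axial_stretch", np.asarray(self.axial_stretch, dtype=float))
        object.__setattr__(self, "poisson", np.asarray(self.poisson, dtype=float))
        t, lam, nu = self.times, self.axial_stretch, self.poisson
        if not (len(t) == len(lam) == len(nu)):
            raise InvalidArgumentError("times/axial_stretch/poisson lengths differ")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("times must be strictly increasing (>= 2 samples)")
        if abs(lam[0] - 1.0) > 1e-12:
            raise InvalidArgumentError("axial stretch must start at 1")
        if np.any(lam < 1.0 - 1e-12):
            raise InvalidArgumentError("axial stretch must stay >= 1")
        if np.any(nu < 0.0) or np.any(nu > 0.5):
            raise InvalidArgumentError("poisson ratio must lie in [0, 0.5]")
        if self.crack is not None:
            op = self.crack.opening_mm
            if len(op) != len(t):
                raise InvalidArgumentError("crack opening must align with schedule times")
            if np.any(op < 0) or np.any(np.diff(op) < -1e-12):
                raise InvalidArgumentError("crack opening must be non-negative and non-decreasing")
            if np.any(op[t < self.crack.onset_s] > 0):
                raise InvalidArgumentError("crack opening must be zero before onset")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def _check_t(self, t: float) -> None:
        t0, t1 = self.span
        if not (t0 - 1e-9 <= t <= t1 + 1e-9):
            raise OutOfRangeError(f"t={t} outside schedule span [{t0}, {t1}]")

    def stretch_at(self, t: float) -> float:
        self._check_t(t)
        return float(np.interp(t, self.times, self.axial_stretch))

    def poisson_at(self, t: float) -> float:
        self._check_t(t)
        return float(np.interp(t, self.times, self.poisson))

    def transverse_stretch_at(self, t: float) -> float:
        lam = self.stretch_at(t)
        return lam ** (-self.poisson_at(t))

    def opening_at(self, t: float) -> float:
        if self.crack is None:
            return 0.0
        self._check_t(t)
        return float(np.interp(t, self.times, self.crack.opening_mm))

    @classmethod
    def ramp(
        cls,
        duration_s: float,
        max_true_strain: float,
        poisson: tuple[float, float] | float = 0.5,
        n_samples: int = 256,
        rate_mode: str = "strain",
        crack: CrackSchedule | None = None,
    ) -> "DeformationSchedule":
        """Monotone extension ramp with a Poisson schedule linear in axial strain.

        ``rate_mode='strain'`` ramps the true strain linearly in time;
        ``rate_mode='stretch'`` ramps the stretch (constant crosshead rate).
        The Poisson ratio interpolates linearly *in axial true strain* between
        the given endpoints (a scalar gives a constant schedule).
        """
        if duration_s <= 0 or max_true_strain < 0:
            raise InvalidArgumentError("duration and max strain must be positive")
        t = np.linspace(0.0, duration_s, n_samples)
        if rate_mode == "strain":
            eps = max_true_strain * t / duration_s
            lam = np.exp(eps)
        elif rate_mode == "stretch":
            lam = 1.0 + (np.expm1(max_true_strain)) * t / duration_s
            eps = np.log(lam)
        else:
            raise InvalidArgumentError(f"unknown rate_mode {rate_mode!r}")
        if np.isscalar(poisson):
            nu = np.full_like(t, float(poisson))  # type: ignore[arg-type]
        else:
            nu0, nu1 = poisson  # type: ignore[misc]
            frac = eps / eps[-1] if eps[-1] > 0 else np.zeros_like(eps)
            nu = nu0 + (nu1 - nu0) * frac
        return cls(times=t, axial_stretch=lam, poisson=nu, crack=crack)


@dataclass(frozen=True)
class MaterialArchetype:
    """Idealized force-response archetype for a tensile specimen.

    ``isotropic`` fractures in a single rapid post-peak drop (brittle,
    homogeneous matrix); ``anisotropic`` fails through a multi-stage
    descending branch (microcrack bridging delayed by the dispersed phase).
    """

    label: str  # "isotropic" | "anisotropic"
    peak_force_n: float
    descending_stages: int = 1
    descending_drops: tuple[float, ...] | None = None  # per-stage relative drops
    noise_sd_n: float = 0.0
    youngs_modulus_pa: float | None = None
    fracture_time_s: float | None = None  # default: crack onset, else 70% of trace

    def __post_init__(self) -> None:
        if self.label not in ("isotropic", "anisotropic"):
            raise InvalidArgumentError("label must be 'isotropic' or 'anisotropic'")
        if self.peak_force_n <= 0:
            raise InvalidArgumentError("peak force must be positive")
        if self.label == "isotropic" and self.descending_stages != 1:
            raise InvalidArgumentError("isotropic archetype has exactly one post-peak drop")
        if self.label == "anisotropic" and self.descending_stages < 2:
            raise InvalidArgumentError("anisotropic archetype needs >= 2 descending stages")
        if self.descending_drops is not None and len(self.descending_drops) != self.descending_stages:
            raise InvalidArgumentError("descending_drops length must match stage count")


@dataclass
class ImageSequence:
    """Grayscale frames on a uniform time base."""

    frames: np.ndarray  # (n, H, W) uint8
    times: np.ndarray  # (n,) seconds
    fps: float
    pixel_scale: float  # mm/px
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def gen_speckle(
    width_px: int,
    height_px: int,
    dot_density: float,
    dot_radius_range: tuple[float, float] = (2.0, 4.0),
    seed: int = 0,
    pixel_scale: float = 0.05,
    blur_sigma: float = 0.8,
) -> SpecklePattern:
    """Random speckle raster: dark anti-aliased dots on a light background.

    ``dot_density`` is the expected dot count per px^2. A mild Gaussian blur
    emulates optical defocus and keeps intensity gradients smooth enough for
    sub-pixel correlation. Deterministic for a fixed seed.
    """
    if width_px < 64 or height_px < 64:
        raise InvalidArgumentError("raster dimensions must be >= 64 px")
    if dot_density <= 0:
        raise InvalidArgumentError("dot density must be positive")
    rmin, rmax = dot_radius_range
    if rmin <= 0 or rmax < rmin:
        raise InvalidArgumentError("dot radii must satisfy 0 < rmin <= rmax")

    rng = np.random.default_rng(seed)
    n_dots = int(round(dot_density * width_px * height_px))
    xs = rng.uniform(0, width_px, n_dots)
    ys = rng.uniform(0, height_px, n_dots)
    radii = rng.uniform(rmin, rmax, n_dots)

    coverage = np.zeros((height_px, width_px), dtype=float)
    for cx, cy, r in zip(xs, ys, radii):
        x0, x1 = int(np.floor(cx - r - 1)), int(np.ceil(cx + r + 2))
        y0, y1 = int(np.floor(cy - r - 1)), int(np.ceil(cy + r + 2))
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, width_px), min(y1, height_px)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx, yy - cy)
        cov = np.clip(r + 0.5 - dist, 0.0, 1.0)  # 1-px anti-aliased rim
        patch = coverage[y0:y1, x0:x1]
        np.maximum(patch, cov, out=patch)

    img = BACKGROUND_INTENSITY - (BACKGROUND_INTENSITY - DOT_INTENSITY) * coverage
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma, mode="nearest")
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SpecklePattern(
        image=img,
        pixel_scale=pixel_scale,
        dot_density=dot_density,
        dot_radius_range=(rmin, rmax),
        seed=seed,
    )


def _deform_params(pattern: SpecklePattern, schedule: DeformationSchedule, t: float):
    lam = schedule.stretch_at(t)
    s_t = schedule.transverse_stretch_at(t)
    h, w = pattern.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    opening_px = schedule.opening_at(t) / pattern.pixel_scale
    if schedule.crack is not None:
        crack_y = cy + schedule.crack.position_mm / pattern.pixel_scale
    else:
        crack_y = np.inf
    return lam, s_t, cy, cx, opening_px, crack_y


def displacement_field(
    pattern: SpecklePattern, schedule: DeformationSchedule, t: float
) -> np.ndarray:
    """Ground-truth forward displacement (u, v) in px at each reference pixel.

    Returns an (H, W, 2) array: ``[..., 0]`` is u (x-displacement),
    ``[..., 1]`` is v (y-displacement). Material below the crack line carries
    the extra rigid opening translation.
    """
    lam, s_t, cy, cx, opening_px, crack_y = _deform_params(pattern, schedule, t)
    h, w = pattern.shape
    y = np.arange(h, dtype=float)[:, None]
    x = np.arange(w, dtype=float)[None, :]
    u = np.broadcast_to((s_t - 1.0) * (x - cx), (h, w)).copy()
    v = np.broadcast_to((lam - 1.0) * (y - cy), (h, w)).copy()
    if opening_px > 0:
        v += opening_px * (y > crack_y)
    out = np.empty((h, w, 2), dtype=np.float64)
    out[..., 0] = u
    out[..., 1] = v
    return out


def warp_frame(
    pattern: SpecklePattern,
    schedule: DeformationSchedule,
    t: float,
    interpolation_order: int = 3,
) -> np.ndarray:
    """Render the deformed speckle frame at time ``t`` (float array, not quantized).

    The reference raster is resampled through the inverse deformation map
    with spline interpolation so sub-pixel displacements are representable.
    Pixels inside an open crack have no material pre-image and are filled with
    a dark constant (the crack interior seen through the opening).
    """
    lam, s_t, cy, cx, opening_px, crack_y = _deform_params(pattern, schedule, t)
    h, w = pattern.shape
    Y = np.arange(h, dtype=float)[:, None]
    X = np.arange(w, dtype=float)[None, :]
    src_x = cx + (X - cx) / s_t
    src_x = np.broadcast_to(src_x, (h, w))
    y_below = cy + (Y - cy) / lam  # candidate pre-image on the upper side
    y_above = cy + (Y - cy - opening_px) / lam  # ... on the lower side
    in_gap = np.zeros((h, w), dtype=bool)
    if opening_px > 0:
        use_above = y_above > crack_y
        src_y = np.where(use_above, y_above, y_below)
        in_gap = np.broadcast_to((~use_above) & (y_below > crack_y), (h, w))
    else:
        src_y = np.broadcast_to(y_below, (h, w))
    src_y = np.broadcast_to(src_y, (h, w))
    warped = ndimage.map_coordinates(
        pattern.image.astype(float),
        [src_y.ravel(), src_x.ravel()],
        order=interpolation_order,
        mode="nearest",
    ).reshape(h, w)
    if np.any(in_gap):
        warped = np.where(in_gap, CRACK_FILL_INTENSITY, warped)
    return warped


def render_sequence(
    pattern: SpecklePattern,
    schedule: DeformationSchedule,
    fps: float = 25.0,
    photometric_noise_sd: float = 0.0,
    seed: int = 0,
    return_ground_truth: bool = True,
) -> tuple[ImageSequence, np.ndarray | None]:
    """Sample the schedule at 1/fps, warp, corrupt, quantize.

    Additive Gaussian photometric noise is applied after warping and the
    result clipped to [0, 255]. Ground truth is the (n, H, W, 2) stack of
    forward displacement maps (float32), or None when not requested.
    """
    if fps <= 0:
        raise InvalidArgumentError("fps must be positive")
    t0, t1 = schedule.span
    n = int(np.floor((t1 - t0) * fps + 0.5)) + 1
    times = t0 + np.arange(n) / fps
    times[-1] = min(times[-1], t1)
    rng = np.random.default_rng(seed)
    h, w = pattern.shape
    frames = np.empty((n, h, w), dtype=np.uint8)
    gt = np.empty((n, h, w, 2), dtype=np.float32) if return_ground_truth else None
    for i, t in enumerate(times):
        img = warp_frame(pattern, schedule, t)
        if photometric_noise_sd > 0:
            img = img + rng.normal(0.0, photometric_noise_sd, img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        if gt is not None:
            gt[i] = displacement_field(pattern, schedule, t)
    seq = ImageSequence(
        frames=frames,
        times=times,
        fps=fps,
        pixel_scale=pattern.pixel_scale,
        meta={
            "seed": seed,
            "photometric_noise_sd": photometric_noise_sd,
            "pattern_seed": pattern.seed,
        },
    )
    return seq, gt


def _rise_profile(eps: np.ndarray, eps_peak: float, sigma_peak: float, modulus: float) -> np.ndarray:
    """True-stress rise: exactly linear (slope = modulus) up to a knee, then a
    monotone concave hand-off whose derivative decays to sigma_peak at the peak.

    With sigma'(eps_peak) = sigma_peak the corresponding force F = sigma A0/lam
    has zero slope exactly at the peak sample, so max(F) lands on the
    constructed fracture point.
    """
    if modulus * eps_peak <= sigma_peak:
        raise InvalidArgumentError(
            "youngs_modulus too small: linear slope must exceed the peak secant"
        )
    eps1 = min(0.5 * sigma_peak / modulus, 0.5 * eps_peak)
    sigma1 = modulus * eps1
    span = eps_peak - eps1
    residual = sigma_peak - sigma1 - sigma_peak * span
    if residual <= 0:
        raise InvalidArgumentError("infeasible rise shape; lower youngs_modulus or peak strain")
    q = (modulus - sigma_peak) * span / residual - 1.0
    if q <= 0:
        raise InvalidArgumentError("youngs_modulus too close to the peak secant")
    sigma = np.where(eps <= eps1, modulus * eps, 0.0)
    knee = eps > eps1
    x = (eps[knee] - eps1) / span
    # integral of sigma' = sigma_peak + (E - sigma_peak) (1-x)^q
    sigma[knee] = (
        sigma1
        + sigma_peak * (eps[knee] - eps1)
        + (modulus - sigma_peak) * span / (q + 1.0) * (1.0 - (1.0 - x) ** (q + 1.0))
    )
    return sigma


def _descending_profile(
    n_post: int, label: str, stages: int, drops: Sequence[float] | None
) -> np.ndarray:
    """Post-peak force levels as fractions of the peak force."""
    if n_post <= 0:
        return np.empty(0)
    if label == "isotropic":
        prof = np.full(n_post, 0.02)
        k = min(2, n_post)
        prof[:k] = np.linspace(1.0, 0.02, k + 1)[1:]  # rapid brittle drop
        if n_post > k:
            tail = np.exp(-np.linspace(0, 5, n_post - k))
            prof[k:] = 0.02 * tail
        return prof
    if drops is None:
        base = [0.45, 0.40, 0.35, 0.30, 0.25]
        drops = base[:stages] if stages <= 5 else list(np.linspace(0.45, 0.2, stages))
    prof = np.empty(n_post)
    # reserve a decaying tail so the last recovery peak stays interior
    n_staged = max(stages, int(round(0.85 * n_post)))
    n_staged = min(n_staged, n_post)
    bounds = np.linspace(0, n_staged, stages + 1).astype(int)
    level = 1.0
    for i in range(stages):
        seg = slice(bounds[i], bounds[i + 1])
        m = bounds[i + 1] - bounds[i]
        if m <= 0:
            continue
        low = level * (1.0 - drops[i])
        kd = min(2, m)
        seg_prof = np.empty(m)
        seg_prof[:kd] = np.linspace(level, low, kd + 1)[1:]
        if m > kd:
            # partial recovery: microcrack bridging arrest -> local maximum
            high = low + 0.25 * (level - low)
            seg_prof[kd:] = np.linspace(low, high, m - kd)
            level = high
        else:
            level = low
        prof[seg] = seg_prof
    if n_staged < n_post:
        prof[n_staged:] = np.linspace(level, 0.02, n_post - n_staged + 1)[1:]
    return prof


def gen_force_trace(
    archetype: MaterialArchetype,
    geometry: SpecimenGeometry,
    schedule: DeformationSchedule,
    sampling_rate_hz: float = 500.0,
    seed: int = 0,
    slippage: tuple[float, float] | None = None,
    time_offset_s: float = 0.0,
) -> ForceTrace:
    """Synthetic texture-analyser trace consistent with the image schedule.

    The force rises (linear, then concave) to ``peak_force_n`` at the fracture
    time, then follows the archetype's descending branch: one rapid brittle
    drop (isotropic) or a staged decline with partial recoveries
    (anisotropic). The crosshead distance column is the machine travel implied
    by the schedule, ``h0 (lambda(t) - 1)``, plus any injected grip slippage
    ``(onset_s, rate_mm_per_s)``. ``time_offset_s`` shifts the recorded clock
    relative to the camera clock (trigger lag).
    """
    if sampling_rate_hz <= 0:
        raise InvalidArgumentError("sampling rate must be positive")
    t0, t1 = schedule.span
    if schedule.crack is not None and schedule.crack.onset_s >= t1:
        raise InvalidArgumentError("crack onset lies after the end of the trace")
    n = int(np.floor((t1 - t0) * sampling_rate_hz)) + 1
    t = t0 + np.arange(n) / sampling_rate_hz

    if archetype.fracture_time_s is not None:
        t_peak = archetype.fracture_time_s
    elif schedule.crack is not None:
        t_peak = schedule.crack.onset_s
    else:
        t_peak = t0 + 0.7 * (t1 - t0)
    if not (t0 < t_peak < t1):
        raise InvalidArgumentError("fracture time must lie inside the trace span")

    lam = np.interp(t, schedule.times, schedule.axial_stretch)
    eps = np.log(lam)
    a0_m2 = geometry.area0_m2
    i_peak = int(np.searchsorted(t, t_peak))
    i_peak = min(max(i_peak, 1), n - 2)
    # align the analytic peak with its sample so the rise profile ends exactly there
    lam_peak = float(lam[i_peak])
    eps_peak = float(eps[i_peak])
    sigma_peak = archetype.peak_force_n * lam_peak / a0_m2
    modulus = archetype.youngs_modulus_pa or 2.0 * sigma_peak / eps_peak
    force = np.empty(n)
    sigma_rise = _rise_profile(eps[: i_peak + 1], eps_peak, sigma_peak, modulus)
    force[: i_peak + 1] = sigma_rise * a0_m2 / lam[: i_peak + 1]
    # pin the constructed peak to the exact peak force
    force[i_peak] = archetype.peak_force_n
    prof = _descending_profile(
        n - i_peak - 1, archetype.label, archetype.descending_stages, archetype.descending_drops
    )
    force[i_peak + 1 :] = archetype.peak_force_n * prof

    if archetype.noise_sd_n > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, archetype.noise_sd_n, n)
        force = np.maximum(force, 0.0)

    distance = geometry.gauge_length_mm * (lam - 1.0)
    if slippage is not None:
        onset, rate = slippage
        distance = distance + np.maximum(t - onset, 0.0) * rate
    return ForceTrace(
        time_s=t + time_offset_s,
        force_n=force,
        distance_mm=distance,
        meta={
            "archetype": archetype.label,
            "peak_force_n": archetype.peak_force_n,
            "fracture_time_s": float(t[i_peak]),
            "fracture_index": i_peak,
            "youngs_modulus_pa": modulus,
            "sigma_peak_pa": sigma_peak,
            "time_offset_s": time_offset_s,
            "sampling_rate_hz": sampling_rate_hz,
        },
    )
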