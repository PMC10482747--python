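"""Subset-based digital image correlation.

A regular grid of square subsets is tracked from the reference frame
(frame 0) through every later frame. Integer-pixel displacement comes from
an exhaustive zero-normalized cross-correlation (ZNCC) search — invariant to
affine intensity changes — seeded per subset with the previous frame's
displacement; sub-pixel refinement is either a quadratic fit to the 3x3
correlation-surface neighbourhood or an iterative gradient-based
(Lucas-Kanade, translation-only) polish of the ZNCC optimum.

Sub-pixel refinement offers three levels: a quadratic fit to the 3x3
correlation-surface neighbourhood, a translation-only Gauss-Newton polish,
and (the default) a first-order subset shape function — each subset may
translate and deform affinely — which keeps the match unbiased when the
strain across a subset reaches several tenths of a pixel. The affine
parameters are discarded after refinement; strain always comes from the
plane fit over neighbouring subsets.

Coordinates are 0-based pixel coordinates: x rightward (axis 1), y downward
(axis 0); the loading axis is y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import (
    DegenerateSubsetError,
    InvalidArgumentError,
    TrackingLostError,
)

__all__ = [
    "SubsetGrid",
    "DicConfig",
    "DisplacementFieldSeries",
    "StrainField",
    "build_grid",
    "match_subset",
    "track_sequence",
    "strain_field",
]

_VAR_EPS = 1e-8  # intensity-variance floor below which a subset is degenerate


@dataclass(frozen=True)
class SubsetGrid:
    """Regular lattice of subset centres inside a rectangular ROI.

    ``roi`` is (y0, y1, x0, x1), half-open pixel intervals. Centres are spaced
    ``step`` px apart; subsets whose window (plus search margin) would
    overhang the image are excluded at construction.
    """

    roi: tuple[int, int, int, int]
    subset_size: int
    step: int
    centers: np.ndarray  # (n, 2) as (y, x)
    image_shape: tuple[int, int]
    grid_shape: tuple[int, int]  # (rows, cols) of the lattice

    @property
    def half(self) -> int:
        return self.subset_size // 2

    def lattice_index(self, k: int) -> tuple[int, int]:
        cols = self.grid_shape[1]
        return divmod(k, cols)


@dataclass(frozen=True)
class DicConfig:
    """Tracking configuration.

    search_radius is the half-width (px) of the integer ZNCC search around
    the seed; correlation_threshold marks a subset invalid once its ZNCC
    drops below it (decorrelation, e.g. near an opening crack); the sub-pixel
    method is 'affine' (first-order shape function, default), 'gradient'
    (translation-only Gauss-Newton) or 'quadratic' (3x3 correlation-surface
    fit).
    """

    subset_size: int = 21
    step: int = 12
    search_radius: int = 5
    correlation_threshold: float = 0.8
    subpixel: str = "affine"
    lk_iterations: int = 10
    lk_tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.subset_size < 11 or self.subset_size % 2 == 0:
            raise InvalidArgumentError("subset_size must be odd and >= 11")
        if self.step <= 0 or self.search_radius <= 0:
            raise InvalidArgumentError("step and search_radius must be positive")
        if self.subpixel not in ("affine", "gradient", "quadratic", "none"):
            raise InvalidArgumentError(
                "subpixel must be 'affine', 'gradient', 'quadratic' or 'none'"
            )


@dataclass
class DisplacementFieldSeries:
    """Per-frame, per-subset displacement relative to the reference frame.

    Frame 0 is the reference: u = v = 0, valid everywhere. Invalid subsets
    carry NaN displacements. Validity is sticky: once a subset decorrelates
    it stays invalid for the rest of the sequence.
    """

    grid: SubsetGrid
    frame_times: np.ndarray  # (n_frames,)
    u: np.ndarray  # (n_frames, n_subsets) px
    v: np.ndarray  # (n_frames, n_subsets) px
    correlation: np.ndarray  # (n_frames, n_subsets)
    valid: np.ndarray  # (n_frames, n_subsets) bool
    config: DicConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def n_subsets(self) -> int:
        return len(self.grid.centers)


@dataclass
class StrainField:
    """Logarithmic (Hencky) strain per subset at one frame."""

    frame_index: int
    exx: np.ndarray
    eyy: np.ndarray
    exy: np.ndarray
    valid: np.ndarray
    window_radius: int  # in subsets


def build_grid(
    image_shape: tuple[int, int],
    roi: tuple[int, int, int, int],
    subset_size: int,
    step: int,
    search_margin: int = 0,
) -> SubsetGrid:
    """Lay a regular lattice of subset centres over the ROI.

    The lattice is centred inside the ROI. Centres whose subset window plus
    ``search_margin`` would overhang the image are dropped; an ROI too small
    for a single subset is an error.
    """
    h, w = image_shape
    y0, y1, x0, x1 = roi
    if subset_size % 2 == 0 or subset_size < 11:
        raise InvalidArgumentError("subset_size must be odd and >= 11")
    if step <= 0:
        raise InvalidArgumentError("step must be positive")
    if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
        raise InvalidArgumentError("roi must lie within the image")
    half = subset_size // 2
    margin = half + search_margin
    lo_y, hi_y = max(y0 + half, margin), min(y1 - 1 - half, h - 1 - margin)
    lo_x, hi_x = max(x0 + half, margin), min(x1 - 1 - half, w - 1 - margin)
    if lo_y > hi_y or lo_x > hi_x:
        raise InvalidArgumentError("roi smaller than one subset (empty grid)")
    n_y = int((hi_y - lo_y) // step) + 1
    n_x = int((hi_x - lo_x) // step) + 1
    # centre the lattice in the admissible span
    off_y = lo_y + ((hi_y - lo_y) - (n_y - 1) * step) // 2
    off_x = lo_x + ((hi_x - lo_x) - (n_x - 1) * step) // 2
    ys = off_y + step * np.arange(n_y)
    xs = off_x + step * np.arange(n_x)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    centers = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(int)
    return SubsetGrid(
        roi=(y0, y1, x0, x1),
        subset_size=subset_size,
        step=step,
        centers=centers,
        image_shape=(h, w),
        grid_shape=(n_y, n_x),
    )


def _zncc_surface(template: np.ndarray, region: np.ndarray) -> np.ndarray:
    """ZNCC of ``template`` against every aligned window of ``region``."""
    t0 = template - template.mean()
    t_norm = np.sqrt((t0 * t0).sum())
    if t_norm < _VAR_EPS:
        raise DegenerateSubsetError("zero-variance subset")
    wins = sliding_window_view(region, template.shape)  # (sy, sx, s, s)
    w_mean = wins.mean(axis=(2, 3))
    num = np.einsum("ijkl,kl->ij", wins, t0)
    w_sq = np.einsum("ijkl,ijkl->ij", wins, wins)
    denom = np.sqrt(np.maximum(w_sq - wins.shape[2] * wins.shape[3] * w_mean**2, 0.0))
    out = np.zeros_like(num)
    good = denom > _VAR_EPS
    out[good] = num[good] / (denom[good] * t_norm)
    return out


def _quadratic_peak(surface: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Sub-pixel offset of the correlation peak from a 3x3 quadratic fit."""
    if not (1 <= iy < surface.shape[0] - 1 and 1 <= ix < surface.shape[1] - 1):
        return 0.0, 0.0
    patch = surface[iy - 1 : iy + 2, ix - 1 : ix + 2]
    dy, dx = np.mgrid[-1:2, -1:2]
    A = np.stack(
        [np.ones(9), dx.ravel(), dy.ravel(), (dx * dx).ravel(), (dx * dy).ravel(), (dy * dy).ravel()],
        axis=1,
    )
    c = np.linalg.lstsq(A, patch.ravel(), rcond=None)[0]
    _, cx, cy, cxx, cxy, cyy = c
    hess = np.array([[2 * cxx, cxy], [cxy, 2 * cyy]])
    det = np.linalg.det(hess)
    if det <= 0:  # not a proper maximum; keep the integer optimum
        return 0.0, 0.0
    off = np.linalg.solve(hess, -np.array([cx, cy]))  # (dx, dy)
    return float(np.clip(off[0], -1, 1)), float(np.clip(off[1], -1, 1))


def _interp_patch(
    image: np.ndarray, cy: float, cx: float, half: int, prefiltered: bool = False
) -> np.ndarray:
    """Cubic-spline sample of a (2h+1)^2 patch centred at (cy, cx).

    ``prefiltered=True`` means ``image`` already holds spline coefficients
    (one :func:`scipy.ndimage.spline_filter` pass per frame instead of one
    per call — the hot path in sequence tracking).
    """
    s = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    coords = [yy.ravel() + cy, xx.ravel() + cx]
    return ndimage.map_coordinates(
        image, coords, order=3, mode="nearest", prefilter=not prefiltered
    ).reshape(s, s)


def _zncc_value(a: np.ndarray, b: np.ndarray) -> float:
    a0 = a - a.mean()
    b0 = b - b.mean()
    na, nb = np.sqrt((a0 * a0).sum()), np.sqrt((b0 * b0).sum())
    if na < _VAR_EPS or nb < _VAR_EPS:
        return 0.0
    return float((a0 * b0).sum() / (na * nb))


def _lk_refine(
    template: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    Hinv: np.ndarray,
    current: np.ndarray,
    center: tuple[float, float],
    u: float,
    v: float,
    half: int,
    iterations: int,
    tol: float,
    prefiltered: bool = False,
) -> tuple[float, float]:
    """Translation-only Gauss-Newton polish of the integer match.

    Solves the linearized brightness-constancy normal equations on the
    reference-subset gradient (template, gradients and inverse Hessian are
    precomputed once per subset); converges in a few iterations because the
    residual displacement after the integer search is below ~1 px.
    """
    cy, cx = center
    ref0 = template - template.mean()
    for _ in range(iterations):
        cur = _interp_patch(current, cy + v, cx + u, half, prefiltered=prefiltered)
        # match mean levels so additive photometric offsets cancel
        diff = (cur - cur.mean()) - ref0
        b = np.array([(gx * diff).sum(), (gy * diff).sum()])
        delta = -Hinv @ b  # Gauss-Newton step on brightness constancy
        u += delta[0]
        v += delta[1]
        if np.hypot(*delta) < tol:
            break
    return u, v


def _subset_gradient(template: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    gy, gx = np.gradient(template)
    H = np.array([[(gx * gx).sum(), (gx * gy).sum()], [(gx * gy).sum(), (gy * gy).sum()]])
    Hinv = np.linalg.inv(H) if np.linalg.det(H) > _VAR_EPS else None
    return gx, gy, Hinv


def _affine_system(template: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Steepest-descent images and inverse Hessian for the affine warp.

    Parameter order: (u, v, axx, axy, ayx, ayy) in the warp
    x' = x + u + axx dx + axy dy, y' = y + v + ayx dx + ayy dy,
    with (dx, dy) offsets from the subset centre.
    """
    half = template.shape[0] // 2
    gy, gx = np.gradient(template)
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    sd = np.stack([gx, gy, gx * dx, gx * dy, gy * dx, gy * dy])  # (6, s, s)
    flat = sd.reshape(6, -1)
    H = flat @ flat.T
    if np.linalg.cond(H) > 1e10:
        return None
    return flat, np.linalg.inv(H), np.stack([dx, dy])


def _affine_refine(
    template: np.ndarray,
    system: tuple[np.ndarray, np.ndarray, np.ndarray],
    current: np.ndarray,
    center: tuple[float, float],
    p: np.ndarray,
    iterations: int,
    tol: float,
    prefiltered: bool = False,
) -> np.ndarray:
    """Gauss-Newton refinement of the six warp parameters.

    ``p`` is (u, v, axx, axy, ayx, ayy); the returned displacement is the
    warp evaluated at the subset centre, i.e. (u, v) itself.
    """
    cy, cx = center
    sd_flat, Hinv, delta = system
    dx, dy = delta
    ref0 = (template - template.mean()).ravel()
    for _ in range(iterations):
        u, v, axx, axy, ayx, ayy = p
        sx = cx + u + (1 + axx) * dx + axy * dy
        sy = cy + v + ayx * dx + (1 + ayy) * dy
        cur = ndimage.map_coordinates(
            current, [sy.ravel(), sx.ravel()], order=3, mode="nearest",
            prefilter=not prefiltered,
        )
        r = (cur - cur.mean()) - ref0
        dp = -Hinv @ (sd_flat @ r)
        p = p + dp
        if np.hypot(dp[0], dp[1]) < tol and np.abs(dp[2:]).max() < tol:
            break
    return p


def _zncc_affine(
    template: np.ndarray,
    image: np.ndarray,
    center: tuple[float, float],
    p: np.ndarray,
    prefiltered: bool,
) -> float:
    half = template.shape[0] // 2
    cy, cx = center
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    u, v, axx, axy, ayx, ayy = p
    sx = cx + u + (1 + axx) * dx + axy * dy
    sy = cy + v + ayx * dx + (1 + ayy) * dy
    cur = ndimage.map_coordinates(
        image, [sy.ravel(), sx.ravel()], order=3, mode="nearest", prefilter=not prefiltered
    ).reshape(template.shape)
    return _zncc_value(template, cur)


def match_subset(
    reference: np.ndarray,
    current: np.ndarray,
    center: tuple[int, int],
    initial_guess: tuple[float, float] = (0.0, 0.0),
    search_radius: int = 5,
    subset_size: int = 21,
    subpixel: str = "gradient",
    lk_iterations: int = 10,
    lk_tol: float = 1e-4,
    current_prefiltered: np.ndarray | None = None,
    initial_affine: np.ndarray | None = None,
    return_affine: bool = False,
):
    """Displacement (u, v) of one subset and the ZNCC at the optimum.

    Exhaustive integer ZNCC search in ``initial_guess +- search_radius``,
    then sub-pixel refinement. ``center`` is (y, x) in the reference frame.
    ``current_prefiltered`` optionally carries the cubic-spline coefficient
    image of ``current`` (computed once per frame by the sequence tracker).
    Raises :class:`DegenerateSubsetError` for a flat (zero-variance) subset.
    """
    ref = np.asarray(reference, dtype=float)
    cur = np.asarray(current, dtype=float)
    cy, cx = center
    half = subset_size // 2
    if not (half <= cy < ref.shape[0] - half and half <= cx < ref.shape[1] - half):
        raise InvalidArgumentError("subset does not fit inside the reference image")
    template = ref[cy - half : cy + half + 1, cx - half : cx + half + 1]

    gy0 = int(round(initial_guess[1]))
    gx0 = int(round(initial_guess[0]))
    # one extra ring so the 3x3 sub-pixel fit has neighbours even when the
    # optimum sits on the nominal search boundary
    r_eff = search_radius + 1
    # clamp the search window into the current image
    y_lo = cy + gy0 - r_eff - half
    y_hi = cy + gy0 + r_eff + half + 1
    x_lo = cx + gx0 - r_eff - half
    x_hi = cx + gx0 + r_eff + half + 1
    y_lo, x_lo = max(y_lo, 0), max(x_lo, 0)
    y_hi, x_hi = min(y_hi, cur.shape[0]), min(x_hi, cur.shape[1])
    region = cur[y_lo:y_hi, x_lo:x_hi]
    if region.shape[0] < subset_size or region.shape[1] < subset_size:
        raise InvalidArgumentError("search window falls outside the current image")
    surface = _zncc_surface(template, region)
    iy, ix = np.unravel_index(np.argmax(surface), surface.shape)
    corr = float(surface[iy, ix])
    u = float(x_lo + ix + half - cx)
    v = float(y_lo + iy + half - cy)

    interp_img = cur if current_prefiltered is None else current_prefiltered
    prefiltered = current_prefiltered is not None
    affine = np.zeros(4) if initial_affine is None else np.asarray(initial_affine, float)
    if subpixel == "quadratic":
        du, dv = _quadratic_peak(surface, iy, ix)
        u, v = u + du, v + dv
    elif subpixel == "gradient":
        du, dv = _quadratic_peak(surface, iy, ix)
        gx, gy, Hinv = _subset_gradient(template)
        if Hinv is not None:
            u, v = _lk_refine(
                template, gx, gy, Hinv, interp_img, (float(cy), float(cx)),
                u + du, v + dv, half, lk_iterations, lk_tol, prefiltered=prefiltered,
            )
        else:
            u, v = u + du, v + dv
    elif subpixel == "affine":
        du, dv = _quadratic_peak(surface, iy, ix)
        system = _affine_system(template)
        if system is not None:
            p = _affine_refine(
                template, system, interp_img, (float(cy), float(cx)),
                np.array([u + du, v + dv, *affine]), lk_iterations, lk_tol,
                prefiltered=prefiltered,
            )
            u, v = float(p[0]), float(p[1])
            affine = p[2:]
        else:
            u, v = u + du, v + dv
    if subpixel == "affine":
        corr = max(corr, _zncc_affine(template, interp_img, (float(cy), float(cx)),
                                      np.array([u, v, *affine]), prefiltered))
    elif subpixel != "none":
        refined = _interp_patch(interp_img, cy + v, cx + u, half, prefiltered=prefiltered)
        corr = max(corr, _zncc_value(template, refined))
    if return_affine:
        return u, v, corr, affine
    return u, v, corr


def track_sequence(sequence, grid: SubsetGrid, config: DicConfig | None = None) -> DisplacementFieldSeries:
    """Track every subset through all frames against the fixed reference.

    Every frame is matched against frame 0; each subset's integer search is
    seeded with its displacement in the previous frame, so the search radius
    only needs to cover the inter-frame increment. Subsets whose correlation
    falls below the threshold are flagged invalid from that frame onward.
    Raises :class:`TrackingLostError` if a frame loses every subset.
    """
    config = config or DicConfig()
    frames = sequence.frames if hasattr(sequence, "frames") else np.asarray(sequence)
    times = (
        np.asarray(sequence.times, dtype=float)
        if hasattr(sequence, "times")
        else np.arange(len(frames), dtype=float)
    )
    n_frames = len(frames)
    if n_frames < 2:
        raise InvalidArgumentError("need at least 2 frames (reference + 1)")
    n_sub = len(grid.centers)
    u = np.full((n_frames, n_sub), np.nan)
    v = np.full((n_frames, n_sub), np.nan)
    corr = np.full((n_frames, n_sub), np.nan)
    valid = np.zeros((n_frames, n_sub), dtype=bool)
    u[0] = v[0] = 0.0
    corr[0] = 1.0
    valid[0] = True

    reference = frames[0].astype(float)
    seed_u = np.zeros(n_sub)
    seed_v = np.zeros(n_sub)
    seed_affine = np.zeros((n_sub, 4))  # warm-starts the shape function
    alive = np.ones(n_sub, dtype=bool)
    for fi in range(1, n_frames):
        cur = frames[fi].astype(float)
        # one spline-coefficient pass per frame serves every subset's
        # sub-pixel interpolation
        cur_coeffs = (
            ndimage.spline_filter(cur, order=3, mode="nearest")
            if config.subpixel != "none"
            else None
        )
        for k in range(n_sub):
            if not alive[k]:
                continue
            cy, cx = grid.centers[k]
            try:
                uk, vk, ck, ak = match_subset(
                    reference,
                    cur,
                    (int(cy), int(cx)),
                    initial_guess=(seed_u[k], seed_v[k]),
                    search_radius=config.search_radius,
                    subset_size=config.subset_size,
                    subpixel=config.subpixel,
                    lk_iterations=config.lk_iterations,
                    lk_tol=config.lk_tol,
                    current_prefiltered=cur_coeffs,
                    initial_affine=seed_affine[k],
                    return_affine=True,
                )
            except (DegenerateSubsetError, InvalidArgumentError):
                alive[k] = False
                continue
            if ck < config.correlation_threshold or not np.isfinite(uk + vk):
                alive[k] = False
                continue
            u[fi, k], v[fi, k], corr[fi, k] = uk, vk, ck
            valid[fi, k] = True
            seed_u[k], seed_v[k] = uk, vk
            seed_affine[k] = ak
        if not valid[fi].any():
            raise TrackingLostError(fi)
    return DisplacementFieldSeries(
        grid=grid,
        frame_times=times,
        u=u,
        v=v,
        correlation=corr,
        valid=valid,
        config=config,
        meta={"coordinate_convention": "0-based px, x rightward, y downward, loading axis y"},
    )


def strain_field(
    fields: DisplacementFieldSeries, frame_index: int, window_radius: int = 2
) -> StrainField:
    """Logarithmic strain per subset from a local least-squares plane fit.

    For each subset, (u, v) of the valid subsets within ``window_radius``
    lattice steps are fit with a plane in (x, y); the fitted displacement
    gradient gives the deformation gradient F = I + grad(u), and the Hencky
    (logarithmic) strain is 0.5 ln(F^T F). Subsets with fewer than 3
    non-collinear valid neighbours are flagged invalid.
    """
    if not (0 <= frame_index < fields.n_frames):
        raise InvalidArgumentError("frame_index out of range")
    grid = fields.grid
    rows, cols = grid.grid_shape
    uu = fields.u[frame_index].reshape(rows, cols)
    vv = fields.v[frame_index].reshape(rows, cols)
    ok = fields.valid[frame_index].reshape(rows, cols)
    cy = grid.centers[:, 0].reshape(rows, cols).astype(float)
    cx = grid.centers[:, 1].reshape(rows, cols).astype(float)

    exx = np.full((rows, cols), np.nan)
    eyy = np.full((rows, cols), np.nan)
    exy = np.full((rows, cols), np.nan)
    valid = np.zeros((rows, cols), dtype=bool)
    r = window_radius
    for i in range(rows):
        for j in range(cols):
            i0, i1 = max(0, i - r), min(rows, i + r + 1)
            j0, j1 = max(0, j - r), min(cols, j + r + 1)
            m = ok[i0:i1, j0:j1]
            if m.sum() < 3:
                continue
            x = cx[i0:i1, j0:j1][m]
            y = cy[i0:i1, j0:j1][m]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # collinear neighbourhood
            A = np.stack([np.ones_like(x), x - x.mean(), y - y.mean()], axis=1)
            coef_u, *_ = np.linalg.lstsq(A, uu[i0:i1, j0:j1][m], rcond=None)
            coef_v, *_ = np.linalg.lstsq(A, vv[i0:i1, j0:j1][m], rcond=None)
            F = np.array(
                [[1.0 + coef_u[1], coef_u[2]], [coef_v[1], 1.0 + coef_v[2]]]
            )
            C = F.T @ F
            w, Q = np.linalg.eigh(C)
            if np.any(w <= 0):
                continue
            E = Q @ np.diag(0.5 * np.log(w)) @ Q.T  # Hencky strain
            exx[i, j], eyy[i, j], exy[i, j] = E[0, 0], E[1, 1], E[0, 1]
            valid[i, j] = True
    return StrainField(
        frame_index=frame_index,
        exx=exx.ravel(),
        eyy=eyy.ravel(),
        exy=exy.ravel(),
        valid=valid.ravel(),
        window_radius=window_radius,
    )
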