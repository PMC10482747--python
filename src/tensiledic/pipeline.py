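"""End-to-end workflow: DIC -> extensometry -> stress-strain -> anisotropy.

``analyze_specimen`` takes one image sequence plus force trace and produces
displacement fields, extensometer series, the dynamic Poisson trajectory,
stress-strain curves under both cross-section models and every available
length source, and the tensile parameters of each curve. ``run_pipeline``
maps it over specimen records, survives per-specimen failures, and pairs
directions into anisotropy indices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dic, extensometry, io, metrics
from .config import RunConfig
from .errors import NoFractureError, TensileDicError
from .geometry import ForceTrace
from .synthetic import ImageSequence

log = logging.getLogger("tensiledic")

__all__ = ["SpecimenResult", "PipelineResult", "analyze_specimen", "run_pipeline"]

AREA_MODELS = ("constant_volume", "dynamic_poisson")
LENGTH_SOURCES = ("machine", "dic_gauge", "dic_crack")


@dataclass
class SpecimenResult:
    id: str
    direction: str
    fields: dic.DisplacementFieldSeries | None = None
    distances: dict[str, extensometry.DistanceSeries] = field(default_factory=dict)
    poisson: extensometry.PoissonTrajectory | None = None
    aligned: pd.DataFrame | None = None
    curves: dict[str, metrics.StressStrainCurve] = field(default_factory=dict)
    parameters: dict[str, metrics.TensileParameters] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    error: str | None = None


@dataclass
class PipelineResult:
    specimens: list[SpecimenResult]
    anisotropy: dict[str, metrics.AnisotropyIndices | None]
    config: RunConfig


def default_roi(
    image_shape: tuple[int, int], config: RunConfig, margin_steps: int = 2
) -> tuple[int, int, int, int]:
    """ROI covering the gauge section and full specimen width, with margin."""
    h, w = image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    half_y = config.geometry.gauge_length_mm / 2.0 / config.pixel_scale
    half_x = config.geometry.width0_mm / 2.0 / config.pixel_scale
    m = margin_steps * config.dic.step
    y0 = int(max(0, np.floor(cy - half_y - m)))
    y1 = int(min(h, np.ceil(cy + half_y + m) + 1))
    x0 = int(max(0, np.floor(cx - half_x - m)))
    x1 = int(min(w, np.ceil(cx + half_x + m) + 1))
    return y0, y1, x0, x1


def build_curves(
    aligned: pd.DataFrame,
    distances: dict[str, extensometry.DistanceSeries],
    config: RunConfig,
) -> dict[str, metrics.StressStrainCurve]:
    """Stress-strain curves for every length source x area model available.

    The machine length source uses the crosshead travel added to the gauge
    length; DIC sources use the extensometer distances directly. The
    dynamic-Poisson area model needs the transverse width series and is
    skipped when it is absent.
    """
    geom = config.geometry
    force = aligned["force_n"].to_numpy()
    h0 = {"machine": geom.gauge_length_mm, "dic_gauge": geom.gauge_length_mm}
    h_series: dict[str, np.ndarray] = {
        "machine": geom.gauge_length_mm + aligned["machine_distance_mm"].to_numpy()
    }
    if "dic_gauge" in aligned:
        h_series["dic_gauge"] = aligned["dic_gauge"].to_numpy()
    if "dic_crack" in aligned and "dic_crack" in distances:
        h_series["dic_crack"] = aligned["dic_crack"].to_numpy()
        h0["dic_crack"] = distances["dic_crack"].nominal_length_mm
    width = aligned["dic_transverse"].to_numpy() if "dic_transverse" in aligned else None

    curves: dict[str, metrics.StressStrainCurve] = {}
    times = aligned["time_s"].to_numpy()
    for source, h in h_series.items():
        good = np.isfinite(h) & (h > 0)
        strain = metrics.true_strain(h0[source], np.where(good, h, h0[source]))
        for model in AREA_MODELS:
            if model == "constant_volume":
                area_mm2 = metrics.area_constant_volume(
                    h0[source], np.where(good, h, h0[source]), geom.area0_mm2
                )
            else:
                if width is None:
                    continue
                w_ok = np.isfinite(width) & (width > 0)
                area_mm2 = metrics.area_dynamic_poisson(
                    np.where(w_ok, width, geom.width0_mm), geom.width0_mm, geom.thickness0_mm
                )
                good = good & w_ok
            stress = metrics.true_stress(force, area_mm2 * 1e-6)
            stress = np.where(good, stress, np.nan)
            curves[f"{source}:{model}"] = metrics.StressStrainCurve(
                strain=strain,
                stress_pa=stress,
                area_model=model,
                length_source=source,
                geometry=geom,
                times=times,
            )
    return curves


def analyze_specimen(
    sequence: ImageSequence,
    trace: ForceTrace,
    config: RunConfig,
    specimen_id: str = "specimen",
    direction: str = "parallel",
    crack_position_px: float | None = None,
) -> SpecimenResult:
    """Run DIC, extensometry and metrics for one specimen."""
    res = SpecimenResult(id=specimen_id, direction=direction)
    t0 = time.perf_counter()
    roi = default_roi(sequence.shape, config)
    grid = dic.build_grid(
        sequence.shape, roi, config.dic.subset_size, config.dic.step,
        search_margin=config.dic.search_radius,
    )
    res.fields = dic.track_sequence(sequence, grid, config.dic)
    res.timings_s["dic"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pixel_scale = config.pixel_scale if not np.isfinite(sequence.pixel_scale) else sequence.pixel_scale
    exts = extensometry.place_extensometers(
        grid,
        config.geometry,
        pixel_scale,
        crack_zone_length_mm=config.extensometry.crack_zone_length_mm,
        crack_position_px=crack_position_px,
    )
    for ext in exts:
        series = extensometry.measure_distance(
            ext, res.fields, pixel_scale,
            idw_radius_factor=config.extensometry.idw_radius_factor,
        )
        res.distances[series.source] = series
    res.poisson = extensometry.poisson_trajectory(
        res.distances["dic_gauge"],
        res.distances["dic_transverse"],
        strain_floor=config.extensometry.axial_strain_floor,
    )
    res.aligned = extensometry.synchronize(
        sequence.times, trace, res.distances,
        time_offset_s=config.extensometry.sync_offset_s,
    )
    res.timings_s["extensometry"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    res.curves = build_curves(res.aligned, res.distances, config)
    for key, curve in res.curves.items():
        try:
            res.parameters[key] = metrics.extract_parameters(
                curve,
                drop_fraction=config.metrics.drop_fraction,
                drop_window=config.metrics.drop_window,
                min_span_strain=config.metrics.min_span_strain,
                r2_floor=config.metrics.r2_floor,
            )
        except (NoFractureError, TensileDicError) as exc:
            log.info("specimen %s curve %s: %s", specimen_id, key, exc)
    res.timings_s["metrics"] = time.perf_counter() - t0
    return res


def _direction_means(
    specimens: list[SpecimenResult], direction: str, curve_key: str
) -> dict[str, float] | None:
    vals = {"fracture_stress": [], "youngs_modulus": [], "toughness": []}
    for s in specimens:
        if s.direction != direction or s.error is not None:
            continue
        p = s.parameters.get(curve_key)
        if p is None:
            continue
        vals["fracture_stress"].append(p.fracture_stress_pa)
        vals["youngs_modulus"].append(p.youngs_modulus_pa)
        vals["toughness"].append(p.toughness_pa)
    if not vals["fracture_stress"]:
        return None
    return {k: float(np.mean(v)) for k, v in vals.items()}


def compute_anisotropy(
    specimens: list[SpecimenResult], curve_key: str
) -> metrics.AnisotropyIndices | None:
    """Direction-paired anisotropy indices from per-direction means."""
    par = _direction_means(specimens, "parallel", curve_key)
    per = _direction_means(specimens, "perpendicular", curve_key)
    if par is None or per is None:
        return None
    return metrics.AnisotropyIndices(
        fracture_stress=metrics.anisotropy_index(
            par["fracture_stress"], per["fracture_stress"]
        ),
        youngs_modulus=metrics.anisotropy_index(
            par["youngs_modulus"], per["youngs_modulus"]
        ),
        toughness=metrics.anisotropy_index(par["toughness"], per["toughness"]),
    )


def run_pipeline(records: list[io.SpecimenRecord], config: RunConfig) -> PipelineResult:
    """Analyse every specimen record and aggregate anisotropy indices.

    A stage failure is attached to its specimen and the run continues; the
    run as a whole fails only when every specimen fails.
    """
    results: list[SpecimenResult] = []
    for rec in records:
        try:
            trace = io.read_force_trace(rec.force_path)
            seq = io.read_image_sequence(rec.sequence_path, fps_override=None)
            cfg = dataclasses.replace(config, geometry=rec.geometry)
            res = analyze_specimen(seq, trace, cfg, specimen_id=rec.id, direction=rec.direction)
        except Exception as exc:  # noqa: BLE001 - per-specimen isolation
            log.warning("specimen %s failed: %s", rec.id, exc)
            res = SpecimenResult(id=rec.id, direction=rec.direction, error=str(exc))
        results.append(res)
    if all(r.error is not None for r in results):
        raise TensileDicError("all specimens failed")
    curve_key = f"{config.metrics.strain_source}:constant_volume"
    if not any(curve_key in r.parameters for r in results if r.error is None):
        curve_key = "machine:constant_volume"
    anis = {curve_key: compute_anisotropy(results, curve_key)}
    return PipelineResult(specimens=results, anisotropy=anis, config=config)


def result_to_json(result: PipelineResult, path: str | Path, ndigits: int = 9) -> None:
    """Serialize scalar results (parameters, anisotropy, config) to JSON."""

    def _round(x):
        return None if x is None or not np.isfinite(x) else round(float(x), ndigits)

    doc: dict = {"config": result.config.to_dict(), "specimens": {}, "anisotropy": {}}
    for s in result.specimens:
        entry: dict = {"direction": s.direction, "error": s.error, "parameters": {}}
        for key, p in s.parameters.items():
            entry["parameters"][key] = {
                "fracture_stress_pa": _round(p.fracture_stress_pa),
                "fracture_strain": _round(p.fracture_strain),
                "youngs_modulus_pa": _round(p.youngs_modulus_pa),
                "toughness_pa": _round(p.toughness_pa),
                "toughness_full_curve_pa": _round(p.toughness_full_curve_pa),
                "fracture_index": p.fracture_index,
                "modulus_r2": _round(p.modulus_r2),
                "modulus_below_floor": p.modulus_below_floor,
            }
        if s.poisson is not None and len(s.poisson.ratio):
            entry["poisson"] = {
                "initial": _round(s.poisson.ratio[0]),
                "final": _round(s.poisson.ratio[-1]),
            }
        doc["specimens"][s.id] = entry
    for key, a in result.anisotropy.items():
        doc["anisotropy"][key] = (
            None
            if a is None
            else {
                "fracture_stress": _round(a.fracture_stress),
                "youngs_modulus": _round(a.youngs_modulus),
                "toughness": _round(a.toughness),
            }
        )
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
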