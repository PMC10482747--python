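"""Readers and writers for instrument and image data.

Force traces arrive as the delimited text exported by the texture analyser;
image sequences as a directory of numbered frames or a video file. All
writers round-trip through plain text (CSV + JSON sidecars) so results stay
inspectable and diffable.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError, SchemaError
from .geometry import ForceTrace, SpecimenGeometry
from .synthetic import ImageSequence

__all__ = [
    "SpecimenRecord",
    "read_force_trace",
    "write_force_trace",
    "read_image_sequence",
    "write_image_sequence",
]

# luma weights for deterministic colour -> grayscale conversion (Rec. 601)
_LUMA = np.array([0.299, 0.587, 0.114])

_DEFAULT_DIALECT = {"time": "time_s", "force": "force_N", "distance": "distance_mm"}


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen: its cutting direction, geometry and data locations."""

    id: str
    direction: str  # 'parallel' | 'perpendicular' to shear flow
    geometry: SpecimenGeometry
    force_path: str | Path | None = None
    sequence_path: str | Path | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("parallel", "perpendicular"):
            raise InvalidArgumentError("direction must be 'parallel' or 'perpendicular'")


def read_force_trace(
    path: str | Path, dialect: dict[str, str] | None = None, sep: str | None = None
) -> ForceTrace:
    """Parse a delimited texture-analyser export into a ForceTrace.

    ``dialect`` maps the logical names time/force/distance to the file's
    column headers (defaults: time_s, force_N, distance_mm; matching is
    case-insensitive and ignores column order). Malformed numeric rows are
    dropped and reported in the trace metadata with their line numbers.
    """
    path = Path(path)
    dialect = {**_DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=sep, engine="python")
    lower = {c.lower().strip(): c for c in df.columns}
    cols = {}
    for logical, header in dialect.items():
        key = header.lower().strip()
        if key not in lower:
            raise SchemaError(f"missing column {header!r} (for {logical}) in {path.name}")
        cols[logical] = lower[key]
    sub = df[[cols["time"], cols["force"], cols["distance"]]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = sub.isna().any(axis=1)
    bad_lines = (sub.index[bad] + 2).tolist()  # +2: header line and 1-based count
    sub = sub[~bad]
    if len(sub) == 0:
        raise DataError(f"no valid rows in {path.name}")
    t = sub[cols["time"]].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise DataError(f"non-monotone time column in {path.name}")
    return ForceTrace(
        time_s=t,
        force_n=sub[cols["force"]].to_numpy(float),
        distance_mm=sub[cols["distance"]].to_numpy(float),
        meta={"path": str(path), "malformed_lines": bad_lines},
    )


def write_force_trace(trace: ForceTrace, path: str | Path) -> None:
    """Write the delimited dialect that :func:`read_force_trace` consumes."""
    df = pd.DataFrame(
        {"time_s": trace.time_s, "force_N": trace.force_n, "distance_mm": trace.distance_mm}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def _frame_number(p: Path) -> int:
    m = re.search(r"(\d+)(?!.*\d)", p.stem)
    return int(m.group(1)) if m else -1


def read_image_sequence(path: str | Path, fps_override: float | None = None) -> ImageSequence:
    """Load a frame directory (numbered PNG/TIFF) or a video file.

    Frames are converted to 8-bit grayscale with fixed luma weights; the
    time base is uniform at ``fps`` (from a ``manifest.json`` sidecar or the
    container metadata unless overridden).
    """
    path = Path(path)
    fps = fps_override
    pixel_scale = np.nan
    meta: dict = {"path": str(path)}
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")],
            key=_frame_number,
        )
        if not files:
            raise InvalidArgumentError(f"no frames found in {path}")
        manifest = path / "manifest.json"
        if manifest.exists():
            doc = json.loads(manifest.read_text())
            fps = fps or doc.get("fps")
            pixel_scale = doc.get("pixel_scale", np.nan)
            meta.update(doc)
        frames = []
        for i, f in enumerate(files):
            try:
                img = iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - report the frame index
                raise OSError(f"unreadable frame {i} ({f.name}): {exc}") from exc
            frames.append(_to_gray(img))
        stack = np.stack(frames)
    else:
        if not path.exists():
            raise InvalidArgumentError(f"no such sequence: {path}")
        try:
            stack = np.stack([_to_gray(im) for im in iio.imiter(path)])
            if fps is None:
                props = iio.immeta(path)
                fps = props.get("fps")
        except OSError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"unreadable video {path}: {exc}") from exc
    if fps is None:
        fps = 25.0
    times = np.arange(len(stack)) / float(fps)
    return ImageSequence(
        frames=stack, times=times, fps=float(fps), pixel_scale=float(pixel_scale), meta=meta
    )


def write_image_sequence(
    seq: ImageSequence,
    directory: str | Path,
    ground_truth: np.ndarray | None = None,
    schedule_doc: dict | None = None,
) -> Path:
    """Write numbered PNG frames plus a JSON manifest (and optional ground truth).

    Ground-truth displacement maps, when given, are stored one ``.npy`` per
    frame next to the images.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(seq)
    width = max(4, len(str(n)))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(directory / f"frame_{i:0{width}d}.png", frame)
        if ground_truth is not None:
            np.save(directory / f"gt_{i:0{width}d}.npy", ground_truth[i])
    manifest = {
        "fps": seq.fps,
        "pixel_scale": seq.pixel_scale,
        "n_frames": n,
        **seq.meta,
    }
    if schedule_doc:
        manifest["schedule"] = schedule_doc
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return directory


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(np.uint8)
    rgb = img[..., :3].astype(float)
    return np.clip(np.rint(rgb @ _LUMA), 0, 255).astype(np.uint8)
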