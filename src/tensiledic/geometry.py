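"""Specimen geometry and the force-trace container.

Geometry is entered in millimetres, as read off the dog-bone mould; stresses
are computed in SI, so :class:`SpecimenGeometry` exposes the initial
cross-section both in mm^2 and m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

MM2_PER_M2 = 1e6


@dataclass(frozen=True)
class SpecimenGeometry:
    """Dog-bone specimen dimensions.

    Parameters
    ----------
    gauge_length_mm:
        Narrow-section length h0 over which strain is nominally measured.
    gap_width_mm:
        Grip-to-grip separation at the start of the test (larger than h0).
    width0_mm, thickness0_mm:
        Initial cross-section of the narrow section.
    """

    gauge_length_mm: float
    gap_width_mm: float
    width0_mm: float
    thickness0_mm: float

    def __post_init__(self) -> None:
        for name in ("gauge_length_mm", "gap_width_mm", "width0_mm", "thickness0_mm"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.gap_width_mm < self.gauge_length_mm:
            raise InvalidArgumentError("gap width must be >= gauge length")

    @property
    def area0_mm2(self) -> float:
        return self.width0_mm * self.thickness0_mm

    @property
    def area0_m2(self) -> float:
        return self.area0_mm2 / MM2_PER_M2


@dataclass
class ForceTrace:
    """Sampled texture-analyser output: time (s), force (N), crosshead travel (mm).

    ``distance_mm`` is the crosshead displacement from the test start, not an
    absolute specimen length.
    """

    time_s: np.ndarray
    force_n: np.ndarray
    distance_mm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.distance_mm = np.asarray(self.distance_mm, dtype=float)
        if not (len(self.time_s) == len(self.force_n) == len(self.distance_mm)):
            raise InvalidArgumentError("time/force/distance lengths differ")
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise InvalidArgumentError("time base must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)
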