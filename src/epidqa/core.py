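"""Core data types shared by the plan builder, renderer, and analyzers.

Coordinate convention (IEC 61217 collimator frame, beam's-eye view):

* ``x`` is the crossplane direction (MLC leaf travel), ``y`` is inplane
  (leaf-pair stacking).  All jaw, leaf, and field positions are millimetres
  projected to the isocenter plane.
* Image arrays are indexed ``(row, col)`` with rows along ``y`` and columns
  along ``x``; the beam central axis (CAX) sits at a fractional pixel index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MLCModel",
    "millennium_120",
    "ControlPoint",
    "Beam",
    "QAPlan",
    "EPIDImage",
    "PlanValidationError",
]


class PlanValidationError(ValueError):
    """A plan, beam, or control point violates a structural invariant."""


@dataclass(frozen=True)
class MLCModel:
    """Leaf-pair geometry of a multileaf collimator.

    ``boundaries_mm`` holds the ``n_pairs + 1`` inplane (y) leaf-edge
    positions at the isocenter plane, strictly increasing; pair ``i`` spans
    ``boundaries_mm[i] .. boundaries_mm[i + 1]``.
    """

    name: str
    boundaries_mm: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries_mm, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise PlanValidationError("boundaries_mm must be a 1-D array of >= 2 edges")
        if not np.all(np.diff(b) > 0):
            raise PlanValidationError("leaf boundaries must be strictly increasing")
        object.__setattr__(self, "boundaries_mm", b)

    @property
    def n_pairs(self) -> int:
        return self.boundaries_mm.size - 1

    def pair_center(self, index: int) -> float:
        """Inplane center (mm) of leaf pair ``index``."""
        return 0.5 * (self.boundaries_mm[index] + self.boundaries_mm[index + 1])

    def pair_span(self, index: int) -> tuple[float, float]:
        return float(self.boundaries_mm[index]), float(self.boundaries_mm[index + 1])

    def pairs_within(self, y_lo: float, y_hi: float) -> list[int]:
        """Indices of leaf pairs whose span lies entirely inside [y_lo, y_hi]."""
        return [
            i
            for i in range(self.n_pairs)
            if self.boundaries_mm[i] >= y_lo - 1e-9 and self.boundaries_mm[i + 1] <= y_hi + 1e-9
        ]


def millennium_120() -> MLCModel:
    """Millennium-120 layout: 10 x 10 mm, 40 x 5 mm, 10 x 10 mm pairs over +/-200 mm."""
    widths = [10.0] * 10 + [5.0] * 40 + [10.0] * 10
    edges = np.concatenate([[-200.0], -200.0 + np.cumsum(widths)])
    return MLCModel(name="Millennium-120", boundaries_mm=edges)


@dataclass
class ControlPoint:
    """One sampled machine state within a beam delivery."""

    meterset_weight: float
    gantry_deg: float = 0.0
    collimator_deg: float = 0.0
    couch_deg: float = 0.0
    jaws: tuple[float, float, float, float] = (-100.0, 100.0, -100.0, 100.0)  # X1,X2,Y1,Y2
    mlc_a: np.ndarray | None = None  # bank A (negative-x side) leaf tips, mm
    mlc_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mlc_a is not None:
            self.mlc_a = np.asarray(self.mlc_a, dtype=float)
        if self.mlc_b is not None:
            self.mlc_b = np.asarray(self.mlc_b, dtype=float)

    def validate(self, n_pairs: int | None = None) -> None:
        x1, x2, y1, y2 = self.jaws
        if x1 > x2 or y1 > y2:
            raise PlanValidationError(f"jaws must satisfy X1<=X2, Y1<=Y2, got {self.jaws}")
        if not 0.0 <= self.meterset_weight <= 1.0 + 1e-9:
            raise PlanValidationError("meterset_weight must lie in [0, 1]")
        for angle, label in ((self.gantry_deg, "gantry"), (self.collimator_deg, "collimator"), (self.couch_deg, "couch")):
            if not 0.0 <= angle < 360.0:
                raise PlanValidationError(f"{label} angle {angle} outside [0, 360)")
        has_a, has_b = self.mlc_a is not None, self.mlc_b is not None
        if has_a != has_b:
            raise PlanValidationError("both MLC banks must be given, or neither")
        if has_a:
            if self.mlc_a.shape != self.mlc_b.shape:
                raise PlanValidationError("MLC banks differ in length")
            if n_pairs is not None and self.mlc_a.size != n_pairs:
                raise PlanValidationError(
                    f"MLC bank length {self.mlc_a.size} does not match model ({n_pairs} pairs)"
                )
            if np.any(self.mlc_a > self.mlc_b + 1e-9):
                raise PlanValidationError("bank A leaf beyond bank B (A <= B required)")


@dataclass
class Beam:
    """Ordered control-point sequence with a meterset."""

    name: str
    control_points: list[ControlPoint]
    mu: float = 100.0

    def validate(self, n_pairs: int | None = None) -> None:
        cps = self.control_points
        if len(cps) < 2:
            raise PlanValidationError(f"beam '{self.name}' needs >= 2 control points")
        weights = [cp.meterset_weight for cp in cps]
        if abs(weights[0]) > 1e-9 or abs(weights[-1] - 1.0) > 1e-9:
            raise PlanValidationError(
                f"beam '{self.name}': cumulative meterset must start at 0 and end at 1"
            )
        if np.any(np.diff(weights) < -1e-12):
            raise PlanValidationError(f"beam '{self.name}': meterset weights must be non-decreasing")
        for i, cp in enumerate(cps):
            try:
                cp.validate(n_pairs)
            except PlanValidationError as exc:
                raise PlanValidationError(f"beam '{self.name}', control point {i}: {exc}") from exc


TEST_TYPES = (
    "open",
    "junction",
    "lightrad",
    "picketfence",
    "dlg",
    "winston_lutz",
    "vmat_t1",
    "vmat_t2",
    "vmat_t3",
)


@dataclass
class QAPlan:
    """A QA test expressed as ordered beams of control points.

    ``metadata`` carries the analyzer-facing expectations a builder records
    (nominal junction line positions, expected picket centers, band ROIs, BB
    layout); it round-trips through DICOM.
    """

    test_type: str
    beams: list[Beam]
    machine_name: str = "LINAC1"
    energy: str = "6X"
    mlc_model: MLCModel = field(default_factory=millennium_120)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.test_type not in TEST_TYPES:
            raise PlanValidationError(f"unknown test_type '{self.test_type}'")
        if not self.beams:
            raise PlanValidationError("plan has no beams")
        for beam in self.beams:
            beam.validate(self.mlc_model.n_pairs)


@dataclass
class EPIDImage:
    """A 2-D portal image plus the detector geometry needed to map pixels to mm.

    Pixel ``(r, c)`` maps to isocenter-plane millimetres as
    ``(r - cax_row) * spacing_row * sad / sid`` (and likewise for columns).
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    sid_mm: float = 1000.0
    sad_mm: float = 1000.0
    cax_pixel: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 32:
            raise ValueError("pixels must be a 2-D grid of at least 32 x 32")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")
        if self.cax_pixel is None:
            self.cax_pixel = ((self.pixels.shape[0] - 1) / 2.0, (self.pixels.shape[1] - 1) / 2.0)

    @property
    def iso_spacing_mm(self) -> tuple[float, float]:
        """Effective pixel spacing back-projected to the isocenter plane."""
        m = self.sad_mm / self.sid_mm
        return (self.pixel_spacing_mm[0] * m, self.pixel_spacing_mm[1] * m)

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Isocenter-plane (y_rows, x_cols) coordinate vectors in mm."""
        sy, sx = self.iso_spacing_mm
        rows = (np.arange(self.pixels.shape[0]) - self.cax_pixel[0]) * sy
        cols = (np.arange(self.pixels.shape[1]) - self.cax_pixel[1]) * sx
        return rows, cols

    def mm_to_index(self, y_mm: float, x_mm: float) -> tuple[float, float]:
        sy, sx = self.iso_spacing_mm
        return (y_mm / sy + self.cax_pixel[0], x_mm / sx + self.cax_pixel[1])


def as_pass_fail(values: Sequence[float], tol: float) -> bool:
    """True when every |value| is within tol."""
    return bool(np.all(np.abs(np.asarray(values, dtype=float)) <= tol))
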