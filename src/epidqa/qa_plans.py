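"""Builders for the periodic linac QA test plans.

Each builder emits a :class:`~epidqa.core.QAPlan` whose control points fully
describe the delivery, plus analyzer-facing expectations in ``plan.metadata``
(nominal junction lines, expected picket centers, VMAT band ROIs, BB layout).
Injected delivery errors (leaf offsets, junction gaps/overlaps) change the
delivered control points only; the recorded expectations stay nominal, which
is what lets the analyzers measure the error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Beam,
    ControlPoint,
    MLCModel,
    PlanValidationError,
    QAPlan,
    millennium_120,
)

__all__ = [
    "PicketFenceSpec",
    "build_open_field_plan",
    "build_junction_plan",
    "build_picketfence_plan",
    "build_lightrad_plan",
    "build_winston_lutz_plan",
    "build_vmat_plans",
    "build_dlg_plan",
    "resample_control_points",
]

_LEAF_PARK_MM = 200.0  # fully retracted leaf position


def _retracted_banks(mlc: MLCModel) -> tuple[np.ndarray, np.ndarray]:
    n = mlc.n_pairs
    return np.full(n, -_LEAF_PARK_MM), np.full(n, _LEAF_PARK_MM)


def _closed_banks(mlc: MLCModel, park_x: float = -150.0) -> tuple[np.ndarray, np.ndarray]:
    n = mlc.n_pairs
    return np.full(n, park_x), np.full(n, park_x)


def _static_beam(
    name: str,
    jaws: tuple[float, float, float, float],
    mlc_a: np.ndarray | None = None,
    mlc_b: np.ndarray | None = None,
    gantry: float = 0.0,
    collimator: float = 0.0,
    couch: float = 0.0,
    mu: float = 100.0,
) -> Beam:
    def cp(w: float) -> ControlPoint:
        return ControlPoint(
            meterset_weight=w,
            gantry_deg=gantry,
            collimator_deg=collimator,
            couch_deg=couch,
            jaws=jaws,
            mlc_a=None if mlc_a is None else mlc_a.copy(),
            mlc_b=None if mlc_b is None else mlc_b.copy(),
        )

    return Beam(name=name, control_points=[cp(0.0), cp(1.0)], mu=mu)


def build_open_field_plan(
    field_size_mm: tuple[float, float] = (100.0, 100.0),
    energy: str = "6X",
    gantry_deg: float = 0.0,
    machine_name: str = "LINAC1",
    mlc: MLCModel | None = None,
) -> QAPlan:
    """Static open field: symmetric jaws, MLC retracted, two control points."""
    mlc = mlc or millennium_120()
    fx, fy = field_size_mm
    if fx <= 0 or fy <= 0:
        raise PlanValidationError("field extents must be positive")
    if fx / 2 > 200 or fy / 2 > 200:
        raise PlanValidationError("field extents must lie within +/-200 mm")
    a, b = _retracted_banks(mlc)
    jaws = (-fx / 2, fx / 2, -fy / 2, fy / 2)
    beam = _static_beam("OPEN", jaws, a, b, gantry=gantry_deg)
    plan = QAPlan(
        test_type="open",
        beams=[beam],
        machine_name=machine_name,
        energy=energy,
        mlc_model=mlc,
        metadata={"field_size_mm": [fx, fy]},
    )
    plan.validate()
    return plan


def build_junction_plan(
    junction_axes: tuple[str, ...] = ("x", "y"),
    half_size_mm: float = 60.0,
    junction_error_mm: float = 0.0,
    energy: str = "6X",
    machine_name: str = "LINAC1",
    mlc: MLCModel | None = None,
) -> QAPlan:
    """Abutting jaw-delimited fields sharing match lines at x=0 and/or y=0.

    ``junction_error_mm`` offsets the shared edges symmetrically: positive
    leaves an unirradiated gap of that width between the nominal edges,
    negative double-exposes an overlap.  With both axes the plan is four
    abutting quadrants; with one axis it is two half fields.
    """
    mlc = mlc or millennium_120()
    axes = tuple(junction_axes)
    if not axes or any(a not in ("x", "y") for a in axes):
        raise PlanValidationError("junction_axes must be a non-empty subset of ('x', 'y')")
    if abs(junction_error_mm) > 10:
        raise PlanValidationError("|junction_error_mm| must be <= 10 mm")
    h = half_size_mm
    e = junction_error_mm / 2.0  # each field's edge recedes by half the gap
    a_bank, b_bank = _retracted_banks(mlc)

    def spans(axis_active: bool) -> list[tuple[float, float]]:
        return [(-h, -e), (e, h)] if axis_active else [(-h, h)]

    beams = []
    for xs in spans("x" in axes):
        for ys in spans("y" in axes):
            name = f"J_X{'-' if xs[0] < -e else '+'}Y{'-' if ys[0] < -e else '+'}"
            beams.append(_static_beam(name, (xs[0], xs[1], ys[0], ys[1]), a_bank, b_bank))
    plan = QAPlan(
        test_type="junction",
        beams=beams,
        machine_name=machine_name,
        energy=energy,
        mlc_model=mlc,
        metadata={
            "junction_lines": {axis: 0.0 for axis in axes},
            "half_size_mm": h,
            "junction_error_mm": junction_error_mm,
        },
    )
    plan.validate()
    return plan


@dataclass
class PicketFenceSpec:
    """Geometry of a DMLC picket-fence delivery.

    A ``gap_mm``-wide slit sweeps in the crossplane direction and dwells at
    ``n_pickets`` evenly spaced stops (``spacing_mm`` center to center),
    painting one high-intensity stripe per stop.
    """

    n_pickets: int = 9
    spacing_mm: float = 15.0
    gap_mm: float = 2.0
    active_pairs: tuple[int, int] | None = None  # inclusive leaf-pair index range
    jaw_margin_mm: float = 10.0

    def picket_centers(self) -> np.ndarray:
        offset = (self.n_pickets - 1) / 2.0
        return (np.arange(self.n_pickets) - offset) * self.spacing_mm

    def validate(self) -> None:
        if self.n_pickets < 2:
            raise PlanValidationError("need at least 2 pickets")
        if self.gap_mm <= 0:
            raise PlanValidationError("gap_mm must be positive")
        if self.spacing_mm <= self.gap_mm:
            raise PlanValidationError("spacing_mm must exceed gap_mm")
        span = (self.n_pickets - 1) * self.spacing_mm / 2 + self.gap_mm / 2 + self.jaw_margin_mm
        if span > 200:
            raise PlanValidationError("pickets do not fit inside the +/-200 mm aperture")


def build_picketfence_plan(
    spec: PicketFenceSpec | None = None,
    leaf_offsets_mm: float | np.ndarray = 0.0,
    y_aperture_mm: float = 100.0,
    energy: str = "6X",
    machine_name: str = "LINAC1",
    mlc: MLCModel | None = None,
) -> QAPlan:
    """DMLC picket fence: the slit dwells at each picket center in turn.

    ``leaf_offsets_mm`` (uniform scalar, or one value per active leaf pair) is
    added to the delivered bank positions only; the expected picket centers
    recorded in metadata stay nominal, mimicking a leaf-positioning error.
    """
    spec = spec or PicketFenceSpec()
    spec.validate()
    mlc = mlc or millennium_120()
    if spec.active_pairs is None:
        pairs = mlc.pairs_within(-y_aperture_mm, y_aperture_mm)
    else:
        lo, hi = spec.active_pairs
        if not (0 <= lo <= hi < mlc.n_pairs):
            raise PlanValidationError("active_pairs outside MLC model range")
        pairs = list(range(lo, hi + 1))
    offsets = np.asarray(leaf_offsets_mm, dtype=float)
    if offsets.ndim == 0:
        offsets = np.full(len(pairs), float(offsets))
    if offsets.size != len(pairs):
        raise PlanValidationError(
            f"leaf_offsets_mm length {offsets.size} != number of active pairs {len(pairs)}"
        )

    centers = spec.picket_centers()
    x_half = centers[-1] + spec.gap_mm / 2 + spec.jaw_margin_mm
    jaws = (-x_half, x_half, float(mlc.boundaries_mm[pairs[0]]), float(mlc.boundaries_mm[pairs[-1] + 1]))

    def banks_at(center: float) -> tuple[np.ndarray, np.ndarray]:
        a, b = _closed_banks(mlc, park_x=-x_half - 20.0)
        for k, p in enumerate(pairs):
            a[p] = center - spec.gap_mm / 2 + offsets[k]
            b[p] = center + spec.gap_mm / 2 + offsets[k]
        return a, b

    cps: list[ControlPoint] = []
    n = spec.n_pickets
    for i, c in enumerate(centers):
        a, b = banks_at(float(c))
        for w in (i / n, (i + 1) / n):  # dwell: weight accrues while the slit is parked
            cps.append(ControlPoint(meterset_weight=w, jaws=jaws, mlc_a=a.copy(), mlc_b=b.copy()))
    beam = Beam(name="PICKET", control_points=cps, mu=200.0)
    plan = QAPlan(
        test_type="picketfence",
        beams=[beam],
        machine_name=machine_name,
        energy=energy,
        mlc_model=mlc,
        metadata={
            "picket_centers_mm": [float(c) for c in centers],
            "active_pairs": [int(p) for p in pairs],
            "gap_mm": spec.gap_mm,
            "spacing_mm": spec.spacing_mm,
        },
    )
    plan.validate()
    return plan


def build_lightrad_plan(
    field_size_mm: tuple[float, float] = (150.0, 150.0),
    inner_offset_mm: float = 5.0,
    outer_offset_mm: float = 25.0,
    energy: str = "6X",
    machine_name: str = "LINAC1",
    mlc: MLCModel | None = None,
) -> QAPlan:
    """Open field plus the light-radiation phantom's nominal BB layout.

    The phantom carries eight ball bearings, two per field side on that
    side's perpendicular bisector: an inner BB ``inner_offset_mm`` inside the
    radiation edge (5 mm nominally) and an outer BB ``outer_offset_mm``
    inside.  BBs are numbered 1-8 clockwise (beam's-eye view) starting from
    the patient-right side, inner ring first.
    """
    plan = build_open_field_plan(field_size_mm, energy=energy, machine_name=machine_name, mlc=mlc)
    hx, hy = field_size_mm[0] / 2.0, field_size_mm[1] / 2.0
    # clockwise in BEV from +x: (+x, -y, -x, +y)
    sides = [((hx, 0.0), (1, 0)), ((0.0, -hy), (0, -1)), ((-hx, 0.0), (-1, 0)), ((0.0, hy), (0, 1))]
    bbs = []
    for role, offset in (("inner", inner_offset_mm), ("outer", outer_offset_mm)):
        for (ex, ey), (ux, uy) in sides:
            bbs.append({
                "index": len(bbs) + 1,
                "role": role,
                "pos_mm": [ex - ux * offset, ey - uy * offset],
            })
    plan.test_type = "lightrad"
    plan.metadata.update({
        "bb_layout": bbs,
        "inner_offset_mm": inner_offset_mm,
        "outer_offset_mm": outer_offset_mm,
    })
    return plan


def build_winston_lutz_plan(
    gantry_collimator_couch_combos: list[tuple[float, float, float]] | None = None,
    field_size_mm: float = 20.0,
    energy: str = "6X",
    machine_name: str = "LINAC1",
    mlc: MLCModel | None = None,
) -> QAPlan:
    """One small MLC/jaw-defined square field per (gantry, collimator, couch) combo."""
    combos = gantry_collimator_couch_combos
    if combos is None:
        combos = [(0.0, 0.0, 0.0), (90.0, 0.0, 0.0), (180.0, 0.0, 0.0), (270.0, 0.0, 0.0)]
    if not combos:
        raise PlanValidationError("need at least one gantry/collimator/couch combo")
    mlc = mlc or millennium_120()
    h = field_size_mm / 2.0
    a, b = _closed_banks(mlc, park_x=-h - 40.0)
    for p in mlc.pairs_within(-h, h):
        a[p], b[p] = -h, h
    jaws = (-h, h, -h, h)
    beams = []
    for i, (g, c, t) in enumerate(combos):
        for angle in (g, c, t):
            if not 0.0 <= angle < 360.0:
                raise PlanValidationError(f"angle {angle} outside [0, 360); normalize first")
        beams.append(_static_beam(f"WL_{i}_G{g:g}C{c:g}T{t:g}", jaws, a, b, gantry=g, collimator=c, couch=t, mu=50.0))
    plan = QAPlan(
        test_type="winston_lutz",
        beams=beams,
        machine_name=machine_name,
        energy=energy,
        mlc_model=mlc,
        metadata={"field_size_mm": field_size_mm, "combos": [list(c) for c in combos]},
    )
    plan.validate()
    return plan


_CARDINAL = (0.0, 90.0, 180.0, 270.0)


def build_vmat_plans(
    which: str,
    band_count: int | None = None,
    inject_mlc_errors: bool = False,
    energy: str = "6X",
    machine_name: str = "LINAC1",
    mlc: MLCModel | None = None,
) -> QAPlan:
    """VMAT constancy test plans.

    ``t1_static_dmlc``: sliding-window field at the four cardinal gantry
    angles.  ``t1_rotating_picket``: picket pattern at cardinal angles plus a
    rotating-gantry delivery (with a documented leaf subset shifted when
    ``inject_mlc_errors`` is set).  ``t2_doserate_gantry`` and ``t3_mlc_speed``:
    banded deliveries whose ROI rectangles are recorded for the band analysis
    (defaults: 7 and 4 bands).
    """
    mlc = mlc or millennium_120()
    y_half = 60.0
    pairs = mlc.pairs_within(-y_half, y_half)

    if which == "t1_static_dmlc":
        beams = [_sliding_window_beam(f"T1_G{g:g}", mlc, pairs, gantry=g, y_half=y_half) for g in _CARDINAL]
        meta = {"reference_gantry_deg": 0.0}
    elif which == "t1_rotating_picket":
        spec = PicketFenceSpec(n_pickets=7, spacing_mm=15.0)
        error_pairs = sorted(set(pairs[::8])) if inject_mlc_errors else []
        beams = [
            _picket_beam(f"T1P_G{g:g}", mlc, pairs, spec, gantry_arc=None, gantry=g)
            for g in _CARDINAL
        ]
        beams.append(_picket_beam("T1P_ARC", mlc, pairs, spec, gantry_arc=(350.0, 10.0)))
        beams.append(
            _picket_beam(
                "T1P_ARC_ERR", mlc, pairs, spec, gantry_arc=(350.0, 10.0),
                error_pairs=error_pairs, error_mm=1.0 if inject_mlc_errors else 0.0,
            )
        )
        meta = {
            "picket_centers_mm": [float(c) for c in spec.picket_centers()],
            "active_pairs": [int(p) for p in pairs],
            "gap_mm": spec.gap_mm,
            "spacing_mm": spec.spacing_mm,
            "error_pairs": [int(p) for p in error_pairs],
            "error_mm": 1.0 if inject_mlc_errors else 0.0,
        }
    elif which in ("t2_doserate_gantry", "t3_mlc_speed"):
        n_bands = band_count or (7 if which.startswith("t2") else 4)
        if n_bands < 2:
            raise PlanValidationError("band_count must be >= 2")
        band_w = 24.0
        x0 = -n_bands * band_w / 2.0
        bands = [(x0 + i * band_w, x0 + (i + 1) * band_w) for i in range(n_bands)]
        # ROI: central 2/3 of each band, central 80% of the inplane aperture
        rois = [
            [lo + band_w / 6, hi - band_w / 6, -0.8 * y_half, 0.8 * y_half]
            for lo, hi in bands
        ]
        beams = [_band_sweep_beam("VMAT_BANDS", mlc, pairs, bands, y_half)]
        beams.append(
            _static_beam(
                "VMAT_OPEN", (x0, -x0, -y_half, y_half), *_retracted_banks(mlc)
            )
        )
        meta = {"band_rois_mm": rois, "band_edges_mm": [list(b) for b in bands], "n_bands": n_bands}
    else:
        raise PlanValidationError(f"unknown VMAT test '{which}'")

    plan = QAPlan(
        test_type={"t1_static_dmlc": "vmat_t1", "t1_rotating_picket": "vmat_t1",
                   "t2_doserate_gantry": "vmat_t2", "t3_mlc_speed": "vmat_t3"}[which],
        beams=beams,
        machine_name=machine_name,
        energy=energy,
        mlc_model=mlc,
        metadata=meta,
    )
    plan.validate()
    return plan


def _sliding_window_beam(name, mlc, pairs, gantry, y_half, slit_mm=20.0, n_steps=11):
    x_half = 50.0
    jaws = (-x_half, x_half, -y_half, y_half)
    centers = np.linspace(-x_half + slit_mm / 2, x_half - slit_mm / 2, n_steps)
    cps = []
    for i, c in enumerate(centers):
        a, b = _closed_banks(mlc, park_x=-x_half - 20.0)
        for p in pairs:
            a[p], b[p] = c - slit_mm / 2, c + slit_mm / 2
        cps.append(ControlPoint(meterset_weight=i / (n_steps - 1), gantry_deg=gantry, jaws=jaws, mlc_a=a, mlc_b=b))
    return Beam(name=name, control_points=cps, mu=150.0)


def _picket_beam(name, mlc, pairs, spec, gantry_arc, gantry=0.0, error_pairs=(), error_mm=0.0):
    centers = spec.picket_centers()
    x_half = centers[-1] + spec.gap_mm / 2 + spec.jaw_margin_mm
    jaws = (-x_half, x_half, float(mlc.boundaries_mm[pairs[0]]), float(mlc.boundaries_mm[pairs[-1] + 1]))
    n = len(centers)
    gantries = (
        np.full(2 * n, gantry)
        if gantry_arc is None
        else np.linspace(gantry_arc[0], gantry_arc[1] + 360.0, 2 * n) % 360.0
    )
    cps = []
    for i, c in enumerate(centers):
        a, b = _closed_banks(mlc, park_x=-x_half - 20.0)
        for p in pairs:
            off = error_mm if p in error_pairs else 0.0
            a[p], b[p] = c - spec.gap_mm / 2 + off, c + spec.gap_mm / 2 + off
        for j, w in enumerate((i / n, (i + 1) / n)):
            cps.append(
                ControlPoint(meterset_weight=w, gantry_deg=float(gantries[2 * i + j]), jaws=jaws, mlc_a=a.copy(), mlc_b=b.copy())
            )
    return Beam(name=name, control_points=cps, mu=150.0)


def _band_sweep_beam(name, mlc, pairs, bands, y_half):
    x_lo, x_hi = bands[0][0], bands[-1][1]
    jaws = (x_lo, x_hi, -y_half, y_half)
    n = len(bands)
    cps = []
    for i, (lo, hi) in enumerate(bands):
        a, b = _closed_banks(mlc, park_x=x_lo - 20.0)
        for p in pairs:
            a[p], b[p] = lo, hi
        for w in (i / n, (i + 1) / n):
            cps.append(ControlPoint(meterset_weight=w, jaws=jaws, mlc_a=a.copy(), mlc_b=b.copy()))
    return Beam(name=name, control_points=cps, mu=150.0)


def build_dlg_plan(
    gap_widths_mm: tuple[float, ...] = (2.0, 4.0, 6.0, 10.0, 14.0, 16.0, 20.0),
    energy: str = "6X",
    machine_name: str = "LINAC1",
    mlc: MLCModel | None = None,
) -> QAPlan:
    """Sweeping-gap deliveries (one beam per gap width) for dosimetric leaf gap work."""
    mlc = mlc or millennium_120()
    y_half = 60.0
    pairs = mlc.pairs_within(-y_half, y_half)
    beams = [
        _sliding_window_beam(f"DLG_{g:g}MM", mlc, pairs, gantry=0.0, y_half=y_half, slit_mm=g)
        for g in gap_widths_mm
        if g > 0
    ]
    if len(beams) != len(gap_widths_mm):
        raise PlanValidationError("gap widths must be positive")
    plan = QAPlan(
        test_type="dlg",
        beams=beams,
        machine_name=machine_name,
        energy=energy,
        mlc_model=mlc,
        metadata={"gap_widths_mm": list(gap_widths_mm)},
    )
    plan.validate()
    return plan


def resample_control_points(plan: QAPlan, max_spacing: float) -> QAPlan:
    """Linearly resample each beam so no consecutive control-point spacing
    exceeds ``max_spacing``.

    The spacing metric is gantry degrees for beams whose gantry moves and
    cumulative meterset weight otherwise.  Jaws, leaves, gantry, and meterset
    are interpolated linearly; original control points are preserved exactly,
    so the operation is idempotent once the bound is met.
    """
    if max_spacing <= 0:
        raise PlanValidationError("max_spacing must be positive")
    plan.validate()
    new_beams = []
    for beam in plan.beams:
        cps = beam.control_points
        gantry = np.array([cp.gantry_deg for cp in cps])
        rotating = np.ptp(gantry) > 1e-9
        out = [cps[0]]
        for lo, hi in zip(cps[:-1], cps[1:]):
            delta = abs(_gantry_delta(lo.gantry_deg, hi.gantry_deg)) if rotating else (
                hi.meterset_weight - lo.meterset_weight
            )
            n_seg = max(1, math.ceil(delta / max_spacing - 1e-9))
            for k in range(1, n_seg):
                out.append(_lerp_cp(lo, hi, k / n_seg))
            out.append(hi)
        new_beams.append(Beam(name=beam.name, control_points=out, mu=beam.mu))
    new_plan = QAPlan(
        test_type=plan.test_type,
        beams=new_beams,
        machine_name=plan.machine_name,
        energy=plan.energy,
        mlc_model=plan.mlc_model,
        metadata=dict(plan.metadata),
    )
    new_plan.validate()
    return new_plan


def _gantry_delta(lo: float, hi: float) -> float:
    """Signed shortest rotation from lo to hi in degrees."""
    return (hi - lo + 180.0) % 360.0 - 180.0


def _lerp_cp(lo: ControlPoint, hi: ControlPoint, t: float) -> ControlPoint:
    def mix(a, b):
        return a + (b - a) * t

    return ControlPoint(
        meterset_weight=mix(lo.meterset_weight, hi.meterset_weight),
        gantry_deg=(lo.gantry_deg + _gantry_delta(lo.gantry_deg, hi.gantry_deg) * t) % 360.0,
        collimator_deg=mix(lo.collimator_deg, hi.collimator_deg),
        couch_deg=mix(lo.couch_deg, hi.couch_deg),
        jaws=tuple(mix(a, b) for a, b in zip(lo.jaws, hi.jaws)),
        mlc_a=None if lo.mlc_a is None else mix(lo.mlc_a, hi.mlc_a),
        mlc_b=None if lo.mlc_b is None else mix(lo.mlc_b, hi.mlc_b),
    )
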