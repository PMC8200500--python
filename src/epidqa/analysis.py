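"""EPID image analysis for the periodic QA tests.

Implements the test statistics and detectors: sub-pixel radiation field edge
location, the jaw-junction intensity statistic, ball-bearing detection for
light-radiation coincidence and Winston-Lutz, picket-fence leaf position
measurement against expected control-point positions, the VMAT band
constancy statistic, and a 2-D global gamma evaluation.

Conventions adopted here (configurable where noted):

* A radiation field edge is the 50% level of the background-subtracted
  plateau, located by linear interpolation on a mean profile.
* The junction statistic ``(I_junc - I_BG) / (I_rad - I_BG) - 1`` samples
  I_junc as the extremum within +/-3 mm of the nominal match line (minimum
  for gaps, maximum for overlaps, whichever is farther from the plateau),
  I_rad from the plateau at least 10 mm from the junction and the field
  edges, and I_BG from the image corners outside the field.  Tolerance
  +/-0.3.
* Picket-fence deviation is signed ``expected - measured`` so a +2 mm leaf
  offset reads as a mean deviation near -2 mm; a leaf passes at 1 mm.
* VMAT bands pass when every band's corrected reading lies within +/-1.5%
  of the mean corrected reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import EPIDImage, MLCModel, QAPlan

__all__ = [
    "AnalysisError",
    "DetectionError",
    "FieldEdges",
    "JunctionResult",
    "LightRadResult",
    "PicketFenceResult",
    "VMATBandResult",
    "GammaResult",
    "WinstonLutzResult",
    "detect_field_edges",
    "junction_statistic",
    "analyze_junction",
    "detect_bbs",
    "analyze_lightrad",
    "analyze_picketfence",
    "analyze_vmat_bands",
    "gamma_2d",
    "analyze_winston_lutz",
]

JUNCTION_TOLERANCE = 0.3
BAND_TOLERANCE_PCT = 1.5
LEAF_TOLERANCE_MM = 1.0
LIGHTRAD_TOLERANCE_MM = 2.0


class AnalysisError(RuntimeError):
    """An analyzer received degenerate or inconsistent input."""


class DetectionError(AnalysisError):
    """An expected image feature (field, stripe, BB) could not be found."""


# --------------------------------------------------------------------------
# field edges


@dataclass(frozen=True)
class FieldEdges:
    """50% radiation field edge positions in isocenter-plane mm."""

    x1: float
    x2: float
    y1: float
    y2: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.x2, self.y1, self.y2)

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) midpoint of the edges."""
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))


def _corner_background(img: np.ndarray, frac: float = 0.06) -> float:
    n = max(4, int(round(min(img.shape) * frac)))
    corners = [img[:n, :n], img[:n, -n:], img[-n:, :n], img[-n:, -n:]]
    return float(np.mean([c.mean() for c in corners]))


def _plateau_level(img: np.ndarray, bg: float | None = None) -> float:
    """Open-field plateau estimate robust to field size and in-field BBs."""
    if bg is None:
        bg = _corner_background(img)
    hi = float(np.percentile(img, 99.9))
    infield = img[img >= bg + 0.5 * (hi - bg)]
    if infield.size == 0:
        return hi
    return float(np.percentile(infield, 80.0))


def _interp_crossings(coord: np.ndarray, profile: np.ndarray, level: float) -> tuple[float, float]:
    """First rising and last falling crossing of `level`, linearly interpolated."""
    above = profile >= level
    idx = np.flatnonzero(above)
    if idx.size == 0:
        raise DetectionError("no profile samples above the 50% level")
    i0, i1 = idx[0], idx[-1]

    def cross(ia: int, ib: int) -> float:
        pa, pb = profile[ia], profile[ib]
        if pb == pa:
            return float(coord[ib])
        t = (level - pa) / (pb - pa)
        return float(coord[ia] + t * (coord[ib] - coord[ia]))

    lo = cross(i0 - 1, i0) if i0 > 0 else float(coord[0])
    hi = cross(i1 + 1, i1) if i1 < profile.size - 1 else float(coord[-1])
    return lo, hi


def detect_field_edges(image: EPIDImage) -> FieldEdges:
    """Locate the four 50% field edges of a single rectangular field.

    Mean profiles are taken over the central half of the field's bounding
    box in the orthogonal direction, so penumbra and BB content near the
    borders do not bias the crossing.
    """
    img = image.pixels
    bg = _corner_background(img)
    plateau = _plateau_level(img, bg)
    if plateau - bg < 10 * max(1e-12, abs(bg)) and plateau - bg < 0.05:
        raise DetectionError("no high-intensity region found")
    level = bg + 0.5 * (plateau - bg)
    mask = img >= level
    rows_any = np.flatnonzero(mask.any(axis=1))
    cols_any = np.flatnonzero(mask.any(axis=0))
    if rows_any.size == 0:
        raise DetectionError("no high-intensity region found")

    def central(idx: np.ndarray) -> slice:
        lo, hi = idx[0], idx[-1]
        quarter = max(1, (hi - lo) // 4)
        return slice(lo + quarter, hi - quarter + 1)

    rows_mm, cols_mm = image.coords_mm()
    x_profile = img[central(rows_any), :].mean(axis=0)
    y_profile = img[:, central(cols_any)].mean(axis=1)
    x1, x2 = _interp_crossings(cols_mm, x_profile, bg + 0.5 * (x_profile.max() - bg))
    y1, y2 = _interp_crossings(rows_mm, y_profile, bg + 0.5 * (y_profile.max() - bg))
    return FieldEdges(x1=x1, x2=x2, y1=y1, y2=y2)


# --------------------------------------------------------------------------
# junction


def junction_statistic(i_junc: float, i_bg: float, i_rad: float) -> float:
    """Dimensionless junction value ``(I_junc - I_BG) / (I_rad - I_BG) - 1``.

    0 means the match-line dose equals the open-field dose; -1 means it fell
    to background.  Passing is within +/-0.3 of zero.
    """
    if i_rad <= i_bg:
        raise AnalysisError("degenerate inputs: I_rad must exceed I_BG")
    return (i_junc - i_bg) / (i_rad - i_bg) - 1.0


@dataclass
class JunctionResult:
    """Per-junction statistics and the worst-case pass/fail decision."""

    junctions: dict[str, float]  # label ('x+', 'x-', 'y+', 'y-') -> junction value
    samples: dict[str, dict]  # label -> {'i_junc', 'i_rad', 'i_bg'}
    tolerance: float = JUNCTION_TOLERANCE

    @property
    def worst_label(self) -> str:
        return max(self.junctions, key=lambda k: abs(self.junctions[k]))

    @property
    def worst_value(self) -> float:
        return self.junctions[self.worst_label]

    @property
    def passed(self) -> bool:
        return abs(self.worst_value) <= self.tolerance


def _band_profile(image: EPIDImage, along: str, band_lo: float, band_hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean profile along `along` ('x' or 'y'), averaged over the orthogonal band [lo, hi] mm."""
    rows_mm, cols_mm = image.coords_mm()
    if along == "x":
        sel = (rows_mm >= band_lo) & (rows_mm <= band_hi)
        return cols_mm, image.pixels[sel, :].mean(axis=0)
    sel = (cols_mm >= band_lo) & (cols_mm <= band_hi)
    return rows_mm, image.pixels[:, sel].mean(axis=1)


def analyze_junction(
    image: EPIDImage,
    plan: QAPlan,
    window_mm: float = 3.0,
    plateau_margin_mm: float = 10.0,
    tolerance: float = JUNCTION_TOLERANCE,
) -> JunctionResult:
    """Evaluate the junction statistic at every nominal match line.

    For each junction axis two profiles are taken, one on each side of the
    field center (offset 5-20 mm so the orthogonal junction, if present,
    does not contaminate the sample), giving up to four junction values.
    """
    lines = plan.metadata.get("junction_lines")
    if not lines:
        raise AnalysisError("plan metadata carries no nominal junction lines")
    half = float(plan.metadata.get("half_size_mm", 60.0))
    i_bg = _corner_background(image.pixels)
    junctions: dict[str, float] = {}
    samples: dict[str, dict] = {}
    for axis, pos in lines.items():
        for sign, band in (("+", (5.0, 20.0)), ("-", (-20.0, -5.0))):
            coord, prof = _band_profile(image, axis, band[0], band[1])
            near = np.abs(coord - pos) <= window_mm
            infield = (np.abs(coord - pos) >= plateau_margin_mm) & (np.abs(coord) <= half - plateau_margin_mm)
            if not near.any() or not infield.any():
                raise AnalysisError("junction/plateau sampling windows are empty")
            i_rad = float(prof[infield].mean())
            lo, hi = float(prof[near].min()), float(prof[near].max())
            v_lo = junction_statistic(lo, i_bg, i_rad)
            v_hi = junction_statistic(hi, i_bg, i_rad)
            value, i_junc = (v_lo, lo) if abs(v_lo) >= abs(v_hi) else (v_hi, hi)
            label = axis + sign
            junctions[label] = value
            samples[label] = {"i_junc": i_junc, "i_rad": i_rad, "i_bg": i_bg}
    return JunctionResult(junctions=junctions, samples=samples, tolerance=tolerance)


# --------------------------------------------------------------------------
# ball bearings


def detect_bbs(
    image: EPIDImage,
    expected_radius_mm: float = 2.0,
    roundness_min: float = 0.85,
    min_dip: float = 0.08,
    edge_margin_mm: float = 3.0,
) -> list[dict]:
    """Find ball-bearing attenuation disks inside the radiation field.

    The local attenuation is isolated by grey-scale closing with a window a
    few BB diameters wide: closing fills BB-sized dark spots while leaving
    the field's own edge roll-off intact, so the dip image ``closed - img``
    is near zero everywhere except at the BBs.  In-field dips of at least
    ``min_dip`` of the field contrast are segmented into connected regions;
    each region is fit to a circle and scored for circularity — the ratio
    of the 5th to the 95th percentile of centroid-to-boundary distances,
    near 1 for a disk, below ~0.8 for squares or elongated blobs large
    enough to survive the penumbra blur — and for size against
    ``expected_radius_mm`` (+/-50%).  Candidates whose centroid lies within ``edge_margin_mm`` of a
    50% field edge are discarded as merged with the penumbra — those BBs are
    reported undetected, not mislocated.

    Returns a (possibly empty) list of dicts with keys ``center_mm`` (x, y),
    ``radius_mm`` and ``roundness``; finding nothing is not an error.
    """
    img = image.pixels
    bg = _corner_background(img)
    plateau = _plateau_level(img, bg)
    level = bg + 0.5 * (plateau - bg)
    field_mask = ndimage.binary_fill_holes(img >= level)
    win = int(round(6.0 * expected_radius_mm / min(image.iso_spacing_mm))) | 1
    closed = ndimage.grey_closing(img, size=(win, win), mode="nearest")
    dip = np.where(field_mask, np.clip(closed - img, 0.0, None), 0.0)
    cand = field_mask & (dip >= min_dip * (plateau - bg))
    # relative attenuation ~ the BB disk itself; dividing out the field shape
    # keeps the weighted centroid unbiased when the BB sits on a dose gradient
    rel = np.where(closed > bg + 0.1 * (plateau - bg), dip / np.maximum(closed, 1e-12), 0.0)
    labels = measure.label(cand)
    edges = detect_field_edges(image)
    rows_mm, cols_mm = image.coords_mm()
    sy, sx = image.iso_spacing_mm
    px_area = sy * sx
    out: list[dict] = []
    for region in measure.regionprops(labels, intensity_image=rel):
        area_mm2 = region.area * px_area
        radius = float(np.sqrt(area_mm2 / np.pi))
        if not (0.5 * expected_radius_mm <= radius <= 1.5 * expected_radius_mm):
            continue
        mask = np.zeros(img.shape, dtype=bool)
        mask[tuple(region.coords.T)] = True
        boundary = mask & ~ndimage.binary_erosion(mask)
        r_c0, c_c0 = region.centroid
        by, bx = np.nonzero(boundary)
        dist = np.hypot((by - r_c0) * sy, (bx - c_c0) * sx)
        if dist.size < 4 or dist.max() <= 0:
            continue
        roundness = float(np.percentile(dist, 5) / np.percentile(dist, 95))
        r_c, c_c = region.centroid_weighted
        y_mm = float(np.interp(r_c, np.arange(rows_mm.size), rows_mm))
        x_mm = float(np.interp(c_c, np.arange(cols_mm.size), cols_mm))
        d_edge = min(x_mm - edges.x1, edges.x2 - x_mm, y_mm - edges.y1, edges.y2 - y_mm)
        if d_edge < edge_margin_mm:
            continue
        # the penumbra distorts a dip region's outline within about two BB
        # diameters of an edge; the shape score is only trusted farther in
        if d_edge >= edge_margin_mm + 2.0 * expected_radius_mm and roundness < roundness_min:
            continue
        out.append({"center_mm": (x_mm, y_mm), "radius_mm": radius, "roundness": roundness})
    return out


@dataclass
class LightRadResult:
    """Light-radiation coincidence: BB centroid to field-edge distances.

    ``deviation_mm`` is ``distance - inner_offset`` for each detected inner
    BB (nominal inner offset 5 mm); indices follow the phantom's clockwise
    1-8 numbering.  Undetected BBs are listed by index with no deviation.
    """

    bb_centers_mm: dict[int, tuple[float, float]]
    bb_edge_distance_mm: dict[int, float]
    deviation_mm: dict[int, float]  # inner BBs only
    undetected: list[int]
    field_edges: FieldEdges
    tolerance_mm: float = LIGHTRAD_TOLERANCE_MM

    @property
    def detected_count(self) -> int:
        return len(self.bb_centers_mm)

    @property
    def passed(self) -> bool:
        if not self.deviation_mm:
            return False
        return all(abs(d) <= self.tolerance_mm for d in self.deviation_mm.values())


def _edge_distance(edges: FieldEdges, x: float, y: float, side: tuple[int, int]) -> float:
    """Signed distance (positive inside) from (x, y) to the given side's edge."""
    ux, uy = side
    if ux > 0:
        return edges.x2 - x
    if ux < 0:
        return x - edges.x1
    if uy > 0:
        return edges.y2 - y
    return y - edges.y1


_SIDES = {1: (1, 0), 2: (0, -1), 3: (-1, 0), 4: (0, 1)}  # BB index mod 4 -> outward normal


def analyze_lightrad(
    image: EPIDImage,
    plan: QAPlan,
    tolerance_mm: float = LIGHTRAD_TOLERANCE_MM,
    match_radius_mm: float = 12.0,
) -> LightRadResult:
    """Measure each BB's distance to its side's 50% radiation edge.

    Detected BBs are matched to the plan's nominal layout by nearest
    neighbour within ``match_radius_mm``; inner BBs get a deviation from the
    nominal inner offset.  The test passes when every detected inner BB's
    |deviation| is within tolerance (and fails if no inner BB is detected).
    """
    layout = plan.metadata.get("bb_layout")
    if not layout:
        raise AnalysisError("plan metadata carries no BB layout")
    inner_offset = float(plan.metadata.get("inner_offset_mm", 5.0))
    edges = detect_field_edges(image)
    radius = plan.metadata.get("bb_diameter_mm", 4.0) / 2.0
    found = detect_bbs(image, expected_radius_mm=radius)
    centers: dict[int, tuple[float, float]] = {}
    distances: dict[int, float] = {}
    deviations: dict[int, float] = {}
    undetected: list[int] = []
    taken: set[int] = set()
    for bb in layout:
        nominal = np.array(bb["pos_mm"], dtype=float)
        best, best_d = None, match_radius_mm
        for k, det in enumerate(found):
            if k in taken:
                continue
            d = float(np.hypot(det["center_mm"][0] - nominal[0], det["center_mm"][1] - nominal[1]))
            if d < best_d:
                best, best_d = k, d
        idx = int(bb["index"])
        if best is None:
            undetected.append(idx)
            continue
        taken.add(best)
        cx, cy = found[best]["center_mm"]
        centers[idx] = (cx, cy)
        side = _SIDES[(idx - 1) % 4 + 1]
        distances[idx] = _edge_distance(edges, cx, cy, side)
        if bb["role"] == "inner":
            deviations[idx] = distances[idx] - inner_offset
    return LightRadResult(
        bb_centers_mm=centers,
        bb_edge_distance_mm=distances,
        deviation_mm=deviations,
        undetected=undetected,
        field_edges=edges,
        tolerance_mm=tolerance_mm,
    )


# --------------------------------------------------------------------------
# picket fence


@dataclass
class PicketFenceResult:
    """Per-leaf picket positions versus expected control-point positions.

    Arrays are shaped (n_active_pairs, n_pickets); NaN marks an undetected
    stripe.  ``deviation_mm = expected - measured`` (a +2 mm delivered
    offset therefore reads near -2 mm).
    """

    active_pairs: list[int]
    expected_mm: np.ndarray
    measured_mm: np.ndarray
    tolerance_mm: float = LEAF_TOLERANCE_MM

    @property
    def deviation_mm(self) -> np.ndarray:
        return self.expected_mm - self.measured_mm

    @property
    def detected(self) -> np.ndarray:
        return np.isfinite(self.measured_mm)

    @property
    def max_single_leaf_deviation_mm(self) -> float:
        dev = np.abs(self.deviation_mm[self.detected])
        return float(dev.max()) if dev.size else float("nan")

    @property
    def picket_spacing_mm(self) -> np.ndarray:
        """Mean measured center-to-center distance per gap (length n_pickets - 1)."""
        diffs = np.diff(self.measured_mm, axis=1)
        return np.nanmean(diffs, axis=0)

    @property
    def mean_deviation_per_picket_mm(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.deviation_mm, axis=0)

    @property
    def percent_passing(self) -> float:
        det = self.detected
        if not det.any():
            return 0.0
        ok = np.abs(self.deviation_mm[det]) <= self.tolerance_mm
        return float(100.0 * ok.mean())

    @property
    def passed(self) -> bool:
        return self.detected.any() and self.percent_passing == 100.0


def _parabolic_peak(coord: np.ndarray, profile: np.ndarray, i: int) -> float:
    """Sub-pixel peak position by parabolic fit through (i-1, i, i+1)."""
    if i == 0 or i == profile.size - 1:
        return float(coord[i])
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a local maximum neighbourhood
        return float(coord[i])
    delta = 0.5 * (y0 - y2) / denom
    step = coord[i + 1] - coord[i]
    return float(coord[i] + delta * step)


def analyze_picketfence(
    image: EPIDImage,
    plan: QAPlan,
    mlc: MLCModel | None = None,
    tolerance_mm: float = LEAF_TOLERANCE_MM,
    band_fraction: float = 0.6,
) -> PicketFenceResult:
    """Locate each leaf pair's picket stripes and compare to expectations.

    For every active leaf pair the crossplane profile is averaged over the
    central ``band_fraction`` of the pair's inplane band; each stripe is the
    sub-pixel (parabolic) maximum within +/- half the picket spacing of its
    expected center, required to rise above half the profile's contrast.
    """
    mlc = mlc or plan.mlc_model
    meta = plan.metadata
    for key in ("picket_centers_mm", "active_pairs", "spacing_mm"):
        if key not in meta:
            raise AnalysisError(f"plan metadata lacks '{key}'")
    centers = np.asarray(meta["picket_centers_mm"], dtype=float)
    pairs = list(meta["active_pairs"])
    spacing = float(meta["spacing_mm"])
    rows_mm, cols_mm = image.coords_mm()
    img = image.pixels
    bg = _corner_background(img)
    # a stripe must rise above half the image-wide stripe plateau; a blank
    # leaf row is then flagged undetected rather than "measured" at noise
    floor = bg + 0.5 * (_plateau_level(img, bg) - bg)
    measured = np.full((len(pairs), centers.size), np.nan)
    for row_i, p in enumerate(pairs):
        lo, hi = mlc.pair_span(p)
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * band_fraction
        sel = (rows_mm >= mid - half) & (rows_mm <= mid + half)
        if not sel.any():
            continue
        prof = img[sel, :].mean(axis=0)
        for k, c in enumerate(centers):
            window = np.abs(cols_mm - c) <= spacing / 2.0
            if not window.any():
                continue
            w_idx = np.flatnonzero(window)
            local = prof[w_idx]
            if local.max() < floor:
                continue  # stripe missing: leaf flagged undetected
            i_peak = w_idx[int(np.argmax(local))]
            measured[row_i, k] = _parabolic_peak(cols_mm, prof, i_peak)
    expected = np.broadcast_to(centers, measured.shape).copy()
    return PicketFenceResult(
        active_pairs=[int(p) for p in pairs],
        expected_mm=expected,
        measured_mm=measured,
        tolerance_mm=tolerance_mm,
    )


# --------------------------------------------------------------------------
# VMAT bands


@dataclass
class VMATBandResult:
    """Band constancy statistics for the dose-rate/gantry-speed and MLC-speed tests."""

    r_test: np.ndarray
    r_open: np.ndarray
    tolerance_pct: float = BAND_TOLERANCE_PCT

    @property
    def corrected(self) -> np.ndarray:
        return self.r_test / self.r_open

    @property
    def percent_diff(self) -> np.ndarray:
        c = self.corrected
        return 100.0 * (c / c.mean() - 1.0)

    @property
    def diff_abs(self) -> float:
        return float(np.abs(self.percent_diff).mean())

    @property
    def passed(self) -> bool:
        return bool(np.all(np.abs(self.percent_diff) <= self.tolerance_pct))


def _roi_mean(image: EPIDImage, roi: tuple[float, float, float, float]) -> float:
    x0, x1, y0, y1 = roi
    r0, c0 = image.mm_to_index(y0, x0)
    r1, c1 = image.mm_to_index(y1, x1)
    rs = slice(int(np.ceil(min(r0, r1))), int(np.floor(max(r0, r1))) + 1)
    cs = slice(int(np.ceil(min(c0, c1))), int(np.floor(max(c0, c1))) + 1)
    block = image.pixels[rs, cs]
    if block.size == 0:
        raise AnalysisError(f"ROI {roi} falls outside the image")
    return float(block.mean())


def analyze_vmat_bands(
    test_image: EPIDImage,
    open_image: EPIDImage,
    band_rois: list[tuple[float, float, float, float]],
    tolerance_pct: float = BAND_TOLERANCE_PCT,
) -> VMATBandResult:
    """Corrected band readings R/R_open and their spread.

    Each band's mean ROI reading is normalized to the open-field delivery to
    cancel beam-shape (off-axis) structure, expressed as a percent
    difference from the mean corrected reading; the summary is the mean of
    absolute percent differences and the test passes when every band is
    within ``tolerance_pct``.
    """
    if len(band_rois) < 2:
        raise AnalysisError("need at least two band ROIs")
    r_t = np.array([_roi_mean(test_image, roi) for roi in band_rois])
    r_o = np.array([_roi_mean(open_image, roi) for roi in band_rois])
    if np.any(r_o <= 0):
        raise AnalysisError("open-field ROI mean must be positive")
    return VMATBandResult(r_test=r_t, r_open=r_o, tolerance_pct=tolerance_pct)


# --------------------------------------------------------------------------
# gamma


@dataclass
class GammaResult:
    """2-D gamma map and pass rate."""

    gamma_map: np.ndarray
    included: np.ndarray  # bool mask of pixels above the low-dose cutoff
    dd_pct: float
    dta_mm: float
    low_dose_cutoff_pct: float

    @property
    def pass_rate_pct(self) -> float:
        g = self.gamma_map[self.included]
        if g.size == 0:
            raise AnalysisError("no pixels above the low-dose cutoff")
        return float(100.0 * np.mean(g <= 1.0))

    @property
    def max_gamma(self) -> float:
        g = self.gamma_map[self.included]
        return float(g.max()) if g.size else float("nan")


def gamma_2d(
    reference: EPIDImage,
    evaluated: EPIDImage,
    dd_pct: float = 3.0,
    dta_mm: float = 3.0,
    low_dose_cutoff_pct: float = 10.0,
    search_radius_factor: float = 3.0,
    search_step_mm: float | None = None,
) -> GammaResult:
    """Global-normalization 2-D gamma of `evaluated` against `reference`.

    The dose difference is normalized to the reference maximum.  For each
    reference pixel the gamma quadratic is minimized over displacements on a
    sub-pixel grid (step ``dta_mm / 4`` unless given) within a disk of
    radius ``search_radius_factor * dta_mm``, sampling the evaluated image
    by bilinear interpolation.  Pixels whose reference dose falls below the
    cutoff are excluded from the pass rate.
    """
    ref = reference.pixels
    ev = evaluated.pixels
    if ref.shape != ev.shape or reference.iso_spacing_mm != evaluated.iso_spacing_mm:
        raise AnalysisError("images must share grid shape and isocenter-plane sampling")
    if dd_pct <= 0 or dta_mm <= 0:
        raise AnalysisError("criteria must be positive")
    d_max = ref.max()
    if d_max <= 0:
        raise AnalysisError("reference image is empty")
    dd_abs = dd_pct / 100.0 * d_max
    sy, sx = reference.iso_spacing_mm
    step = search_step_mm if search_step_mm is not None else dta_mm / 4.0
    radius = search_radius_factor * dta_mm
    n_steps = int(np.floor(radius / step))
    offsets = [
        (dy * step, dx * step)
        for dy in range(-n_steps, n_steps + 1)
        for dx in range(-n_steps, n_steps + 1)
        if (dy * step) ** 2 + (dx * step) ** 2 <= radius**2 + 1e-12
    ]
    rr, cc = np.meshgrid(np.arange(ref.shape[0], dtype=float),
                         np.arange(ref.shape[1], dtype=float), indexing="ij")
    gamma_sq = np.full(ref.shape, np.inf)
    for dy, dx in offsets:
        coords = np.array([rr + dy / sy, cc + dx / sx])
        sample = ndimage.map_coordinates(ev, coords, order=1, mode="constant", cval=np.nan)
        dist_term = (dy**2 + dx**2) / dta_mm**2
        with np.errstate(invalid="ignore"):
            cost = (sample - ref) ** 2 / dd_abs**2 + dist_term
        cost = np.where(np.isnan(cost), np.inf, cost)
        np.minimum(gamma_sq, cost, out=gamma_sq)
    gamma_map = np.sqrt(gamma_sq)
    included = ref >= low_dose_cutoff_pct / 100.0 * d_max
    return GammaResult(
        gamma_map=gamma_map,
        included=included,
        dd_pct=dd_pct,
        dta_mm=dta_mm,
        low_dose_cutoff_pct=low_dose_cutoff_pct,
    )


# --------------------------------------------------------------------------
# Winston-Lutz


@dataclass
class WinstonLutzResult:
    """BB-to-radiation-field-center offset for one Winston-Lutz image."""

    bb_center_mm: tuple[float, float]
    field_center_mm: tuple[float, float]
    field_edges: FieldEdges

    @property
    def offset_vector_mm(self) -> tuple[float, float]:
        return (
            self.bb_center_mm[0] - self.field_center_mm[0],
            self.bb_center_mm[1] - self.field_center_mm[1],
        )

    @property
    def offset_magnitude_mm(self) -> float:
        return float(np.hypot(*self.offset_vector_mm))


def analyze_winston_lutz(image: EPIDImage, expected_bb_radius_mm: float = 2.0) -> WinstonLutzResult:
    """Field center (midpoint of the 50% edges) versus the BB centroid."""
    edges = detect_field_edges(image)
    found = detect_bbs(image, expected_radius_mm=expected_bb_radius_mm)
    if not found:
        raise DetectionError("no ball bearing found in the Winston-Lutz image")
    fx, fy = edges.center
    best = min(found, key=lambda d: np.hypot(d["center_mm"][0] - fx, d["center_mm"][1] - fy))
    return WinstonLutzResult(bb_center_mm=best["center_mm"], field_center_mm=(fx, fy), field_edges=edges)
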