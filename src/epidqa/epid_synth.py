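"""Synthetic EPID image renderer.

Stands in for linac acquisition so every analyzer can be exercised offline.
Images are composed directly in isocenter-plane millimetres on the detector
grid (avoiding double magnification bookkeeping): field edges are error
functions of width ``penumbra_sigma_mm``, ball bearings are blurred circular
attenuation disks, and DMLC deliveries are integrated control point by
control point weighted by meterset.  Every renderer is deterministic given
(plan, config, error, seed).

The model deliberately omits scatter, EPID glare/ghosting, MLC
tongue-and-groove, and rounded leaf ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .core import Beam, EPIDImage, QAPlan

__all__ = [
    "ErrorModel",
    "RenderConfig",
    "render_open_field",
    "render_junction_image",
    "render_lightrad_image",
    "render_picketfence_image",
    "render_band_image",
    "render_winston_lutz_image",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class ErrorModel:
    """Injectable delivery errors.

    ``leaf_offset_mm`` is a uniform scalar or one value per active leaf pair
    (order of the plan's ``active_pairs`` metadata) added to both delivered
    bank positions.  ``junction_error_mm`` is a signed jaw miscalibration at
    the match line: positive opens a gap, negative an overlap.
    ``phantom_shift_mm`` translates the light-rad phantom in its own plane
    and ``ssd_mm`` sets its source-to-surface distance (1000 mm puts the
    phantom in the isocenter plane).  ``band_perturbation`` multiplies each
    VMAT band's intensity.  ``noise_sigma`` is Gaussian noise relative to
    the open-field plateau.
    """

    leaf_offset_mm: float | np.ndarray = 0.0
    junction_error_mm: float = 0.0
    phantom_shift_mm: tuple[float, float] = (0.0, 0.0)
    ssd_mm: float = 1000.0
    band_perturbation: np.ndarray | None = None
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.ssd_mm <= 0:
            raise ValueError("ssd_mm must be positive")
        if self.band_perturbation is not None:
            self.band_perturbation = np.asarray(self.band_perturbation, dtype=float)
            if np.any(self.band_perturbation <= 0):
                raise ValueError("band perturbation multipliers must be > 0")


@dataclass
class RenderConfig:
    """Detector grid and image-formation parameters."""

    grid_shape: tuple[int, int] = (512, 512)
    pixel_spacing_mm: tuple[float, float] = (0.5, 0.5)  # at the detector plane
    sid_mm: float = 1000.0
    sad_mm: float = 1000.0
    penumbra_sigma_mm: float = 1.5
    background_level: float = 0.02  # fraction of the open-field plateau
    bb_contrast: float = 0.25  # relative attenuation of a ball bearing
    bb_diameter_mm: float = 4.0
    offaxis_bow: float = 0.0  # fractional radial intensity droop at the grid corner

    def __post_init__(self) -> None:
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra_sigma_mm must be > 0")

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Isocenter-plane (Y, X) mm coordinates of every pixel (2-D, broadcast)."""
        m = self.sad_mm / self.sid_mm
        ny, nx = self.grid_shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_spacing_mm[0] * m
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_spacing_mm[1] * m
        return y[:, None], x[None, :]


def _edge_profile(coord: np.ndarray, lo: float, hi: float, sigma: float) -> np.ndarray:
    """1 inside [lo, hi], 0 outside, erf roll-off of width sigma; 50% at lo and hi."""
    return 0.5 * (erf((coord - lo) / (sigma * _SQRT2)) - erf((coord - hi) / (sigma * _SQRT2)))


def _rect(y, x, jaws, sigma):
    x1, x2, y1, y2 = jaws
    return _edge_profile(x, x1, x2, sigma) * _edge_profile(y, y1, y2, sigma)


def _shape_factor(y, x, config: RenderConfig) -> np.ndarray:
    if config.offaxis_bow == 0.0:
        return np.ones(np.broadcast_shapes(y.shape, x.shape))
    m = config.sad_mm / config.sid_mm
    ry = (config.grid_shape[0] - 1) / 2.0 * config.pixel_spacing_mm[0] * m
    rx = (config.grid_shape[1] - 1) / 2.0 * config.pixel_spacing_mm[1] * m
    return 1.0 - config.offaxis_bow * (y**2 + x**2) / (ry**2 + rx**2)


def _finalize(fluence: np.ndarray, config: RenderConfig, error: ErrorModel | None,
              seed: int | None, meta: dict) -> EPIDImage:
    bg = config.background_level
    img = bg + (1.0 - bg) * fluence
    sigma = error.noise_sigma if error is not None else 0.0
    if sigma > 0:
        if seed is None and error is not None:
            seed = error.seed
        rng = np.random.default_rng(seed)
        img = img + sigma * rng.standard_normal(img.shape)
    return EPIDImage(
        pixels=np.clip(img, 0.0, None),
        pixel_spacing_mm=config.pixel_spacing_mm,
        sid_mm=config.sid_mm,
        sad_mm=config.sad_mm,
        meta=meta,
    )


def render_open_field(beam: Beam, config: RenderConfig | None = None,
                      error: ErrorModel | None = None, seed: int | None = None) -> EPIDImage:
    """Render a static jaw-defined beam: plateau 1.0 with erf edges at the jaws."""
    config = config or RenderConfig()
    y, x = config.grids()
    jaws = beam.control_points[0].jaws
    fl = _rect(y, x, jaws, config.penumbra_sigma_mm) * _shape_factor(y, x, config)
    meta = {"test_type": "open", "gantry_deg": beam.control_points[0].gantry_deg}
    return _finalize(fl, config, error, seed, meta)


def render_junction_image(plan: QAPlan, config: RenderConfig | None = None,
                          error: ErrorModel | None = None, seed: int | None = None) -> EPIDImage:
    """Sum of the abutting half-field (or quadrant) renders.

    An additional ``error.junction_error_mm`` recedes (gap) or advances
    (overlap) every jaw edge abutting a junction line by half the error, on
    top of whatever error the plan itself was built with.
    """
    config = config or RenderConfig()
    y, x = config.grids()
    lines = plan.metadata.get("junction_lines", {})
    extra = (error.junction_error_mm if error is not None else 0.0) / 2.0
    fl = np.zeros(config.grid_shape)
    near = 6.0  # a jaw within this distance of a junction line abuts it
    for beam in plan.beams:
        x1, x2, y1, y2 = beam.control_points[0].jaws
        if "x" in lines:
            jx = lines["x"]
            if abs(x2 - jx) < near:
                x2 -= extra
            if abs(x1 - jx) < near:
                x1 += extra
        if "y" in lines:
            jy = lines["y"]
            if abs(y2 - jy) < near:
                y2 -= extra
            if abs(y1 - jy) < near:
                y1 += extra
        fl += _rect(y, x, (x1, x2, y1, y2), config.penumbra_sigma_mm)
    fl *= _shape_factor(y, x, config)
    meta = {"test_type": "junction", "junction_lines": dict(lines)}
    return _finalize(fl, config, error, seed, meta)


def render_lightrad_image(plan: QAPlan, config: RenderConfig | None = None,
                          error: ErrorModel | None = None, seed: int | None = None) -> EPIDImage:
    """Open field with the phantom's BB attenuation disks.

    BBs live in the phantom plane at ``error.ssd_mm``; their pattern projects
    onto the isocenter plane scaled by SAD/SSD and translated by the phantom
    shift, while the radiation field edges stay put.
    """
    config = config or RenderConfig()
    error = error or ErrorModel()
    y, x = config.grids()
    jaws = plan.beams[0].control_points[0].jaws
    fl = _rect(y, x, jaws, config.penumbra_sigma_mm)
    scale = config.sad_mm / error.ssd_mm
    sx, sy = error.phantom_shift_mm
    radius = config.bb_diameter_mm / 2.0 * scale
    for bb in plan.metadata["bb_layout"]:
        bx = (bb["pos_mm"][0] + sx) * scale
        by = (bb["pos_mm"][1] + sy) * scale
        d = np.sqrt((x - bx) ** 2 + (y - by) ** 2)
        disk = 0.5 * (1.0 - erf((d - radius) / (config.penumbra_sigma_mm * _SQRT2)))
        fl = fl * (1.0 - config.bb_contrast * disk)
    fl *= _shape_factor(y, x, config)
    meta = {"test_type": "lightrad", "ssd_mm": error.ssd_mm}
    return _finalize(fl, config, error, seed, meta)


def _leaf_offsets_full(error: ErrorModel | None, plan: QAPlan) -> np.ndarray:
    """Per-pair render-time leaf offsets (length n_pairs)."""
    n = plan.mlc_model.n_pairs
    out = np.zeros(n)
    if error is None:
        return out
    off = np.asarray(error.leaf_offset_mm, dtype=float)
    if off.ndim == 0:
        active = plan.metadata.get("active_pairs")
        if active is None:
            out[:] = float(off)
        else:
            out[np.asarray(active, dtype=int)] = float(off)
    else:
        active = plan.metadata.get("active_pairs")
        if active is None or len(active) != off.size:
            raise ValueError("per-leaf offsets must match the plan's active_pairs")
        out[np.asarray(active, dtype=int)] = off
    return out


def _integrate_dmlc(beam: Beam, plan: QAPlan, config: RenderConfig,
                    leaf_off: np.ndarray) -> np.ndarray:
    """Meterset-weighted sum of per-segment apertures (midpoint rule)."""
    y, x = config.grids()
    sigma = config.penumbra_sigma_mm
    bounds = plan.mlc_model.boundaries_mm
    fl = np.zeros(config.grid_shape)
    cps = beam.control_points
    # cache inplane leaf-band profiles per pair index on first use
    band_cache: dict[int, np.ndarray] = {}
    for lo, hi in zip(cps[:-1], cps[1:]):
        dw = hi.meterset_weight - lo.meterset_weight
        if dw <= 1e-12:
            continue
        a = 0.5 * (lo.mlc_a + hi.mlc_a) + leaf_off
        b = 0.5 * (lo.mlc_b + hi.mlc_b) + leaf_off
        jaws = tuple(0.5 * (u + v) for u, v in zip(lo.jaws, hi.jaws))
        seg = np.zeros(config.grid_shape)
        for p in range(a.size):
            if b[p] - a[p] < 1e-6:
                continue  # closed pair
            if p not in band_cache:
                band_cache[p] = _edge_profile(y, bounds[p], bounds[p + 1], sigma)
            seg += band_cache[p] * _edge_profile(x, a[p], b[p], sigma)
        seg *= _rect(y, x, jaws, sigma)
        fl += dw * seg
    return fl


def render_picketfence_image(plan: QAPlan, config: RenderConfig | None = None,
                             error: ErrorModel | None = None, seed: int | None = None) -> EPIDImage:
    """Integrated DMLC picket-fence delivery.

    High-intensity stripes appear at the delivered slit centers (nominal
    picket centers plus any plan-level or render-time leaf offsets).  The
    image is normalized so the tallest stripe's plateau is 1.
    """
    config = config or RenderConfig()
    leaf_off = _leaf_offsets_full(error, plan)
    fl = _integrate_dmlc(plan.beams[0], plan, config, leaf_off)
    peak = fl.max()
    if peak > 0:
        fl = fl / peak
    fl *= _shape_factor(*config.grids(), config)
    meta = {"test_type": "picketfence"}
    return _finalize(fl, config, error, seed, meta)


def render_band_image(plan: QAPlan, config: RenderConfig | None = None,
                      error: ErrorModel | None = None, seed: int | None = None,
                      open_field: bool = False) -> EPIDImage:
    """VMAT dose-rate / MLC-speed band delivery (or its open-field companion).

    Band b's intensity is multiplied by ``error.band_perturbation[b]``; the
    off-axis shape factor applies identically to the band image and the open
    companion, so the analyzer's R/R_open correction cancels it.
    """
    config = config or RenderConfig()
    y, x = config.grids()
    sigma = config.penumbra_sigma_mm
    bands = plan.metadata["band_edges_mm"]
    jaws = None
    for beam in plan.beams:
        if beam.name == "VMAT_OPEN":
            jaws = beam.control_points[0].jaws
    if jaws is None:
        x_lo, x_hi = bands[0][0], bands[-1][1]
        jaws = plan.beams[0].control_points[0].jaws
    if open_field:
        fl = _rect(y, x, jaws, sigma)
    else:
        pert = error.band_perturbation if error is not None and error.band_perturbation is not None \
            else np.ones(len(bands))
        if pert.size != len(bands):
            raise ValueError("band_perturbation length must equal the band count")
        y_prof = _edge_profile(y, jaws[2], jaws[3], sigma)
        fl = np.zeros(config.grid_shape)
        for (lo, hi), m in zip(bands, pert):
            fl += m * _edge_profile(x, lo, hi, sigma) * y_prof
    fl *= _shape_factor(y, x, config)
    meta = {"test_type": plan.test_type, "open_field": open_field}
    return _finalize(fl, config, error, seed, meta)


def render_winston_lutz_image(plan: QAPlan, config: RenderConfig | None = None,
                              error: ErrorModel | None = None, seed: int | None = None,
                              beam_index: int = 0,
                              bb_offset_mm: tuple[float, float] = (0.0, 0.0)) -> EPIDImage:
    """Small square field with a single BB near the beam axis.

    ``bb_offset_mm`` (x, y) displaces the BB from the radiation isocenter,
    emulating an isocenter walkout; ``error.phantom_shift_mm`` adds to it.
    """
    config = config or RenderConfig()
    error = error or ErrorModel()
    y, x = config.grids()
    jaws = plan.beams[beam_index].control_points[0].jaws
    fl = _rect(y, x, jaws, config.penumbra_sigma_mm)
    bx = bb_offset_mm[0] + error.phantom_shift_mm[0]
    by = bb_offset_mm[1] + error.phantom_shift_mm[1]
    d = np.sqrt((x - bx) ** 2 + (y - by) ** 2)
    disk = 0.5 * (1.0 - erf((d - config.bb_diameter_mm / 2.0) / (config.penumbra_sigma_mm * _SQRT2)))
    fl = fl * (1.0 - config.bb_contrast * disk)
    meta = {"test_type": "winston_lutz",
            "gantry_deg": plan.beams[beam_index].control_points[0].gantry_deg}
    return _finalize(fl, config, error, seed, meta)
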