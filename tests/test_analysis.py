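import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from epidqa import (
    AnalysisError,
    DetectionError,
    EPIDImage,
    ErrorModel,
    analyze_junction,
    analyze_lightrad,
    analyze_picketfence,
    analyze_vmat_bands,
    analyze_winston_lutz,
    build_junction_plan,
    build_open_field_plan,
    build_picketfence_plan,
    build_winston_lutz_plan,
    detect_bbs,
    detect_field_edges,
    gamma_2d,
    junction_statistic,
    render_junction_image,
    render_lightrad_image,
    render_open_field,
    render_picketfence_image,
    render_winston_lutz_image,
)
from epidqa.analysis import VMATBandResult


class TestJunctionStatistic:
    def test_field_level_reads_zero(self):
        assert junction_statistic(100.0, 10.0, 100.0) == 0.0

    def test_background_level_reads_minus_one(self):
        assert junction_statistic(10.0, 10.0, 100.0) == -1.0

    def test_hand_computed_case(self):
        # (80 - 10) / (100 - 10) - 1 = 70/90 - 1
        assert junction_statistic(80.0, 10.0, 100.0) == pytest.approx(70.0 / 90.0 - 1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AnalysisError):
            junction_statistic(50.0, 100.0, 100.0)

    @given(
        i_junc=st.floats(0.0, 200.0),
        i_bg=st.floats(0.0, 50.0),
        i_rad=st.floats(60.0, 200.0),
        gain=st.floats(0.1, 10.0),
        offset=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_intensity_invariance(self, i_junc, i_bg, i_rad, gain, offset):
        """The statistic is unchanged by any I -> g*I + c with g > 0."""
        base = junction_statistic(i_junc, i_bg, i_rad)
        mapped = junction_statistic(gain * i_junc + offset, gain * i_bg + offset, gain * i_rad + offset)
        assert mapped == pytest.approx(base, abs=1e-9)


class TestAnalyzeJunction:
    def _value(self, error_mm, config):
        plan = build_junction_plan(junction_error_mm=error_mm)
        img = render_junction_image(plan, config)
        return analyze_junction(img, plan)

    def test_matched_junction_passes(self, config):
        res = self._value(0.0, config)
        assert abs(res.worst_value) < 0.1
        assert res.passed
        assert len(res.junctions) == 4  # both axes, both sides

    def test_four_mm_overlap_fails_high(self, config):
        res = self._value(-4.0, config)
        assert res.worst_value > 0.3
        assert not res.passed

    def test_four_mm_gap_fails_low(self, config):
        res = self._value(4.0, config)
        assert res.worst_value < -0.3
        assert not res.passed

    def test_monotone_in_injected_gap(self, config):
        values = [self._value(e, config).worst_value for e in (-4.0, -2.0, 0.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(values[:-1], values[1:]))


class TestFieldEdges:
    def test_hundred_mm_field_edges(self, config):
        img = render_open_field(build_open_field_plan((100.0, 100.0)).beams[0], config)
        e = detect_field_edges(img)
        assert e.as_tuple() == pytest.approx((-50.0, 50.0, -50.0, 50.0), abs=0.1)

    def test_translation_equivariance(self, config):
        plan = build_open_field_plan((100.0, 100.0))
        for cp in plan.beams[0].control_points:
            x1, x2, y1, y2 = cp.jaws
            cp.jaws = (x1 + 3.0, x2 + 3.0, y1, y2)
        e = detect_field_edges(render_open_field(plan.beams[0], config))
        assert (e.x1, e.x2) == pytest.approx((-47.0, 53.0), abs=0.1)
        assert (e.y1, e.y2) == pytest.approx((-50.0, 50.0), abs=0.1)

    def test_uniform_image_raises(self):
        img = EPIDImage(np.full((64, 64), 0.5), pixel_spacing_mm=(0.5, 0.5))
        with pytest.raises(DetectionError):
            detect_field_edges(img)


class TestDetectBBs:
    def test_all_eight_bbs_found_near_injection(self, lightrad_plan, lightrad_image):
        found = detect_bbs(lightrad_image, expected_radius_mm=2.0)
        assert len(found) == 8
        nominal = [tuple(bb["pos_mm"]) for bb in lightrad_plan.metadata["bb_layout"]]
        for det in found:
            d = min(np.hypot(det["center_mm"][0] - nx, det["center_mm"][1] - ny)
                    for nx, ny in nominal)
            assert d < 0.2

    def test_square_object_rejected_by_roundness(self, config):
        # 8 mm square: large enough that the penumbra blur does not round it
        # into a disk; its equivalent-area radius matches the expected BB size
        beam = build_open_field_plan((150.0, 150.0)).beams[0]
        img = render_open_field(beam, config)
        y, x = config.grids()
        square = (np.abs(x - 30.0) < 4.0) & (np.abs(y) < 4.0)
        pixels = img.pixels * np.where(square, 0.75, 1.0)
        marked = EPIDImage(pixels, pixel_spacing_mm=img.pixel_spacing_mm, sid_mm=img.sid_mm)
        centers = [d["center_mm"] for d in detect_bbs(marked, expected_radius_mm=4.5)]
        assert not any(abs(cx - 30.0) < 5.0 and abs(cy) < 5.0 for cx, cy in centers)
        # a disk of the same equivalent radius at the same spot is accepted
        d = np.sqrt((x - 30.0) ** 2 + y**2)
        pixels = img.pixels * np.where(d < 4.5, 0.75, 1.0)
        disk = EPIDImage(pixels, pixel_spacing_mm=img.pixel_spacing_mm, sid_mm=img.sid_mm)
        centers = [d["center_mm"] for d in detect_bbs(disk, expected_radius_mm=4.5)]
        assert any(abs(cx - 30.0) < 1.0 and abs(cy) < 1.0 for cx, cy in centers)

    def test_bb_straddling_edge_not_returned(self, lightrad_plan, config):
        # at a short SSD the magnified inner BBs land on the field edge
        img = render_lightrad_image(lightrad_plan, config, ErrorModel(ssd_mm=950.0))
        found = detect_bbs(img, expected_radius_mm=2.0)
        rows = detect_field_edges(img)
        for det in found:  # whatever remains is well inside the field
            cx, cy = det["center_mm"]
            assert min(cx - rows.x1, rows.x2 - cx, cy - rows.y1, rows.y2 - cy) > 2.9
        assert len(found) == 4  # only the outer ring survives


class TestAnalyzeLightRad:
    def test_nominal_deviations_near_zero(self, lightrad_plan, lightrad_image):
        res = analyze_lightrad(lightrad_image, lightrad_plan)
        assert res.detected_count == 8
        assert len(res.deviation_mm) == 4
        for dev in res.deviation_mm.values():
            assert abs(dev) < 0.2
        assert res.passed

    def test_ssd_deviation_matches_projection_oracle(self, lightrad_plan, config):
        ssd = 1050.0
        img = render_lightrad_image(lightrad_plan, config, ErrorModel(ssd_mm=ssd))
        res = analyze_lightrad(img, lightrad_plan)
        # projection oracle: BB at 70 mm maps to 70 * SAD/SSD; edge stays at 75
        expected = (75.0 - 70.0 * 1000.0 / ssd) - 5.0
        for dev in res.deviation_mm.values():
            assert dev == pytest.approx(expected, abs=0.25)
        assert not res.passed

    def test_phantom_shift_antisymmetric_deviations(self, lightrad_plan, config):
        img = render_lightrad_image(lightrad_plan, config, ErrorModel(phantom_shift_mm=(1.5, 0.0)))
        res = analyze_lightrad(img, lightrad_plan)
        # BB 1 is on the +x side (distance shrinks), BB 3 on the -x side
        assert res.deviation_mm[1] == pytest.approx(-1.5, abs=0.25)
        assert res.deviation_mm[3] == pytest.approx(1.5, abs=0.25)

    def test_missing_layout_is_analysis_error(self, lightrad_image):
        with pytest.raises(AnalysisError):
            analyze_lightrad(lightrad_image, build_open_field_plan())


class TestAnalyzePicketFence:
    def test_nominal_spacing_and_full_pass(self, picket_plan, picket_image):
        res = analyze_picketfence(picket_image, picket_plan)
        np.testing.assert_allclose(res.picket_spacing_mm, 15.0, atol=0.1)
        assert res.percent_passing == 100.0
        assert res.max_single_leaf_deviation_mm < 0.2

    def test_uniform_offset_recovered_with_table_sign(self, picket_plan, config):
        img = render_picketfence_image(picket_plan, config,
                                       ErrorModel(leaf_offset_mm=2.0, noise_sigma=0.01, seed=42))
        res = analyze_picketfence(img, picket_plan)
        assert np.nanmean(res.deviation_mm) == pytest.approx(-2.0, abs=0.1)
        assert res.percent_passing == 0.0

    @pytest.mark.parametrize("offset", [-2.0, -1.5, -0.5, 0.5, 1.5, 2.0])
    def test_offset_recovery_within_015mm(self, picket_plan, config, offset):
        img = render_picketfence_image(picket_plan, config,
                                       ErrorModel(leaf_offset_mm=offset, noise_sigma=0.01, seed=9))
        res = analyze_picketfence(img, picket_plan)
        assert np.nanmean(res.deviation_mm) == pytest.approx(-offset, abs=0.15)

    def test_single_pair_offset_localized(self, picket_plan, config):
        n = len(picket_plan.metadata["active_pairs"])
        offsets = np.zeros(n)
        offsets[7] = 1.5
        img = render_picketfence_image(picket_plan, config, ErrorModel(leaf_offset_mm=offsets))
        res = analyze_picketfence(img, picket_plan)
        failing_rows = set(np.flatnonzero((np.abs(res.deviation_mm) > 1.0).any(axis=1)))
        assert failing_rows == {7}

    def test_missing_stripe_flagged_not_failed(self, picket_plan, picket_image):
        pixels = picket_image.pixels.copy()
        pair = picket_plan.metadata["active_pairs"][0]
        lo, hi = picket_plan.mlc_model.pair_span(pair)
        rows, _ = picket_image.coords_mm()
        pixels[(rows >= lo) & (rows <= hi), :] = 0.02  # blank that pair's band
        img = EPIDImage(pixels, pixel_spacing_mm=picket_image.pixel_spacing_mm,
                        sid_mm=picket_image.sid_mm)
        res = analyze_picketfence(img, picket_plan)
        assert not res.detected[0].any()
        assert res.detected[1:].all()
        assert res.percent_passing == 100.0  # undetected leaves leave the denominator


class TestAnalyzeVMATBands:
    def _image(self, values):
        px = np.repeat(np.asarray(values, dtype=float), 16)[None, :].repeat(64, axis=0)
        return EPIDImage(px, pixel_spacing_mm=(1.0, 1.0))

    def _rois(self, n):
        # image columns span 16 mm per band, centered on the CAX
        return [(-8.0 * n + 16 * b + 2, -8.0 * n + 16 * (b + 1) - 2, -20.0, 20.0) for b in range(n)]

    def test_identical_bands_pass_with_zero_diff(self):
        res = analyze_vmat_bands(self._image([1, 1, 1, 1]), self._image([1, 1, 1, 1]), self._rois(4))
        np.testing.assert_allclose(res.percent_diff, 0.0, atol=1e-12)
        assert res.diff_abs == 0.0
        assert res.passed

    def test_hand_computed_case(self):
        # corrected (1.00, 1.00, 1.02, 0.98): diffs (0, 0, +2, -2), Diff_ABS = 1, fail
        res = analyze_vmat_bands(self._image([1.0, 1.0, 1.02, 0.98]),
                                 self._image([1, 1, 1, 1]), self._rois(4))
        np.testing.assert_allclose(res.percent_diff, [0.0, 0.0, 2.0, -2.0], atol=1e-9)
        assert res.diff_abs == pytest.approx(1.0, abs=1e-9)
        assert not res.passed

    def test_global_scale_invariance(self):
        a = analyze_vmat_bands(self._image([1.0, 1.01, 0.99]), self._image([1, 1, 1]), self._rois(3))
        b = analyze_vmat_bands(self._image([1.07, 1.07 * 1.01, 1.07 * 0.99]),
                               self._image([0.5, 0.5, 0.5]), self._rois(3))
        np.testing.assert_allclose(a.percent_diff, b.percent_diff, atol=1e-9)

    @given(st.lists(st.floats(0.5, 2.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_signed_diffs_average_to_zero(self, readings):
        res = VMATBandResult(r_test=np.asarray(readings), r_open=np.ones(len(readings)))
        assert res.percent_diff.mean() == pytest.approx(0.0, abs=1e-9)


def brute_force_gamma(ref_img, ev_img, dd_pct, dta_mm, step):
    """Independent exhaustive gamma: python loops + hand-rolled bilinear interp."""
    ref, ev = ref_img.pixels, ev_img.pixels
    sy, sx = ref_img.iso_spacing_mm
    dd = dd_pct / 100.0 * ref.max()
    radius = 3.0 * dta_mm
    n = int(np.floor(radius / step))
    out = np.zeros_like(ref)

    def interp(r, c):
        if r < 0 or c < 0 or r > ev.shape[0] - 1 or c > ev.shape[1] - 1:
            return None
        r0, c0 = int(np.floor(r)), int(np.floor(c))
        r1, c1 = min(r0 + 1, ev.shape[0] - 1), min(c0 + 1, ev.shape[1] - 1)
        fr, fc = r - r0, c - c0
        return (ev[r0, c0] * (1 - fr) * (1 - fc) + ev[r1, c0] * fr * (1 - fc)
                + ev[r0, c1] * (1 - fr) * fc + ev[r1, c1] * fr * fc)

    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            best = np.inf
            for di in range(-n, n + 1):
                for dj in range(-n, n + 1):
                    dy, dx = di * step, dj * step
                    if dy * dy + dx * dx > radius * radius + 1e-12:
                        continue
                    val = interp(i + dy / sy, j + dx / sx)
                    if val is None:
                        continue
                    cost = (val - ref[i, j]) ** 2 / dd**2 + (dy * dy + dx * dx) / dta_mm**2
                    best = min(best, cost)
            out[i, j] = np.sqrt(best)
    return out


class TestGamma:
    def test_identical_images_all_pass(self, config):
        img = render_open_field(build_open_field_plan().beams[0], config)
        res = gamma_2d(img, img)
        assert res.pass_rate_pct == 100.0
        assert res.max_gamma == 0.0

    def test_uniform_dose_scale_at_criterion(self):
        rng = np.random.default_rng(0)
        base = np.full((48, 48), 1.0) + 0.0 * rng.standard_normal((48, 48))
        ref = EPIDImage(base, pixel_spacing_mm=(1.0, 1.0))
        ev = EPIDImage(base * 1.03, pixel_spacing_mm=(1.0, 1.0))
        res = gamma_2d(ref, ev, dd_pct=3.0, dta_mm=3.0, low_dose_cutoff_pct=10.0)
        # flat interior: |delta D| / dd exactly 1, no distance credit needed
        interior = res.gamma_map[8:-8, 8:-8]
        assert np.all(interior <= 1.0 + 1e-9)
        assert interior.max() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (32, 32)
        ref = EPIDImage(rng.uniform(0.2, 1.0, shape), pixel_spacing_mm=(1.0, 1.0))
        ev = EPIDImage(np.clip(ref.pixels + rng.normal(0, 0.05, shape), 0, None),
                       pixel_spacing_mm=(1.0, 1.0))
        step = 0.75
        res = gamma_2d(ref, ev, dd_pct=3.0, dta_mm=3.0, search_step_mm=step)
        oracle = brute_force_gamma(ref, ev, 3.0, 3.0, step)
        np.testing.assert_allclose(res.gamma_map, oracle, atol=1e-6)

    def test_mismatched_geometry_rejected(self):
        a = EPIDImage(np.ones((32, 32)), pixel_spacing_mm=(1.0, 1.0))
        b = EPIDImage(np.ones((32, 32)), pixel_spacing_mm=(0.5, 0.5))
        with pytest.raises(AnalysisError):
            gamma_2d(a, b)


class TestWinstonLutz:
    def test_centered_bb_zero_offset(self, config):
        plan = build_winston_lutz_plan()
        img = render_winston_lutz_image(plan, config)
        res = analyze_winston_lutz(img)
        assert res.offset_magnitude_mm == pytest.approx(0.0, abs=0.1)

    def test_injected_offset_recovered(self, config):
        plan = build_winston_lutz_plan()
        img = render_winston_lutz_image(plan, config, bb_offset_mm=(1.0, 0.0))
        res = analyze_winston_lutz(img)
        assert res.offset_vector_mm[0] == pytest.approx(1.0, abs=0.1)
        assert res.offset_vector_mm[1] == pytest.approx(0.0, abs=0.1)

    def test_no_bb_is_detection_error(self, config):
        img = render_open_field(build_winston_lutz_plan().beams[0], config)
        with pytest.raises(DetectionError):
            analyze_winston_lutz(img)
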