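import json

import numpy as np
import pydicom
import pytest

from epidqa import (
    EPIDImage,
    FormatError,
    MetadataError,
    PlanValidationError,
    SchemaError,
    UnsupportedBeamError,
    build_junction_plan,
    build_lightrad_plan,
    build_open_field_plan,
    build_picketfence_plan,
    build_vmat_plans,
    build_winston_lutz_plan,
    load_field_instructions,
    read_epid_image,
    read_rtplan,
    render_open_field,
    write_epid_image,
    write_rtplan,
)
from epidqa.qa_plans import PicketFenceSpec, resample_control_points


def _assert_plans_equal(a, b):
    assert a.test_type == b.test_type
    assert a.energy == b.energy
    assert len(a.beams) == len(b.beams)
    assert np.allclose(a.mlc_model.boundaries_mm, b.mlc_model.boundaries_mm)
    for ba, bb in zip(a.beams, b.beams):
        assert len(ba.control_points) == len(bb.control_points)
        assert ba.mu == pytest.approx(bb.mu)
        for ca, cb in zip(ba.control_points, bb.control_points):
            assert ca.meterset_weight == pytest.approx(cb.meterset_weight, abs=1e-6)
            assert np.allclose(ca.jaws, cb.jaws, atol=1e-6)
            assert ca.gantry_deg == pytest.approx(cb.gantry_deg, abs=1e-6)
            if ca.mlc_a is not None:
                assert np.allclose(ca.mlc_a, cb.mlc_a, atol=1e-6)
                assert np.allclose(ca.mlc_b, cb.mlc_b, atol=1e-6)
    assert json.dumps(a.metadata, sort_keys=True, default=float) == \
        json.dumps(b.metadata, sort_keys=True, default=float)


BUILDERS = [
    build_open_field_plan,
    build_junction_plan,
    build_lightrad_plan,
    build_picketfence_plan,
    build_winston_lutz_plan,
    lambda: build_vmat_plans("t2_doserate_gantry"),
    lambda: build_vmat_plans("t1_rotating_picket", inject_mlc_errors=True),
]


class TestRTPlanRoundTrip:
    @pytest.mark.parametrize("builder", BUILDERS)
    def test_round_trip_is_identity(self, builder, tmp_path):
        plan = builder()
        path = write_rtplan(plan, tmp_path / "plan.dcm", seed=1)
        _assert_plans_equal(plan, read_rtplan(path))

    def test_deterministic_bytes_for_fixed_seed(self, tmp_path):
        p1 = write_rtplan(build_picketfence_plan(), tmp_path / "a.dcm", seed=7)
        p2 = write_rtplan(build_picketfence_plan(), tmp_path / "b.dcm", seed=7)
        assert p1.read_bytes() == p2.read_bytes()

    def test_control_point_count_preserved_for_fine_arc(self, tmp_path):
        # vendor-style VMAT arc: 177 control points over a 358-degree sweep
        from epidqa.core import Beam, ControlPoint, QAPlan

        n = 177
        weights = np.linspace(0.0, 1.0, n)
        gantry = (181.0 + np.linspace(0.0, 358.0, n)) % 360.0
        cps = [ControlPoint(meterset_weight=float(w), gantry_deg=float(g))
               for w, g in zip(weights, gantry)]
        plan = QAPlan(test_type="vmat_t1", beams=[Beam(name="ARC", control_points=cps)])
        assert len(plan.beams[0].control_points) == 177
        path = write_rtplan(plan, tmp_path / "arc.dcm")
        ds = pydicom.dcmread(str(path))  # independent DICOM dump
        assert int(ds.BeamSequence[0].NumberOfControlPoints) == 177
        assert len(read_rtplan(path).beams[0].control_points) == 177

    def test_invalid_plan_rejected_with_location(self, tmp_path):
        plan = build_picketfence_plan()
        plan.beams[0].control_points[3].meterset_weight = 0.0
        with pytest.raises(PlanValidationError, match="PICKET"):
            write_rtplan(plan, tmp_path / "bad.dcm")

    def test_missing_beam_sequence_is_format_error(self, tmp_path):
        path = write_rtplan(build_open_field_plan(), tmp_path / "p.dcm")
        ds = pydicom.dcmread(str(path))
        del ds.BeamSequence
        ds.save_as(str(path))
        with pytest.raises(FormatError, match="BeamSequence"):
            read_rtplan(path)

    def test_electron_only_plan_unsupported(self, tmp_path):
        path = write_rtplan(build_open_field_plan(), tmp_path / "p.dcm")
        ds = pydicom.dcmread(str(path))
        ds.BeamSequence[0].RadiationType = "ELECTRON"
        ds.save_as(str(path))
        with pytest.raises(UnsupportedBeamError):
            read_rtplan(path)

    def test_unknown_label_read_as_open_with_warning(self, tmp_path):
        path = write_rtplan(build_open_field_plan(), tmp_path / "p.dcm")
        ds = pydicom.dcmread(str(path))
        # strip the private payload and label so the test type must be inferred
        del ds[0x3261, 0x0010]
        del ds[0x3261, 0x1001]
        ds.RTPlanName = "MYSTERY"
        ds.save_as(str(path))
        with pytest.warns(UserWarning, match="open"):
            plan = read_rtplan(path)
        assert plan.test_type == "open"


class TestEPIDImageIO:
    @pytest.fixture()
    def image(self):
        return render_open_field(build_open_field_plan().beams[0])

    @pytest.mark.parametrize("name", ["img.dcm", "img.json"])
    def test_round_trip(self, image, tmp_path, name):
        path = write_epid_image(image, tmp_path / name)
        back = read_epid_image(path)
        # DICOM stores 16-bit scaled intensities; sidecar is exact
        atol = 1e-4 if name.endswith(".dcm") else 1e-12
        np.testing.assert_allclose(back.pixels, image.pixels, atol=atol)
        assert back.pixel_spacing_mm == image.pixel_spacing_mm
        assert back.sid_mm == image.sid_mm
        assert back.cax_pixel == image.cax_pixel

    def test_isocenter_spacing_from_sid(self, tmp_path):
        img = EPIDImage(np.zeros((64, 64)), pixel_spacing_mm=(0.336, 0.336), sid_mm=1500.0)
        path = write_epid_image(img, tmp_path / "i.json")
        assert read_epid_image(path).iso_spacing_mm == pytest.approx((0.224, 0.224))

    def test_missing_pixel_spacing_is_metadata_error(self, image, tmp_path):
        path = write_epid_image(image, tmp_path / "img.dcm")
        ds = pydicom.dcmread(str(path))
        del ds.ImagePlanePixelSpacing
        ds.save_as(str(path))
        with pytest.raises(MetadataError, match="spacing"):
            read_epid_image(path)

    def test_missing_sid_defaults_and_flags(self, image, tmp_path):
        path = write_epid_image(image, tmp_path / "img.dcm")
        ds = pydicom.dcmread(str(path))
        del ds.RTImageSID
        ds.save_as(str(path))
        back = read_epid_image(path)
        assert back.sid_mm == 1000.0
        assert back.meta["sid_defaulted"] is True

    def test_unreadable_file_is_format_error(self, tmp_path):
        bad = tmp_path / "junk.dcm"
        bad.write_bytes(b"not dicom at all")
        with pytest.raises(FormatError):
            read_epid_image(bad)


class TestFieldInstructions:
    def test_parametric_picketfence_equals_builder(self, tmp_path):
        doc = {"test_type": "picketfence", "params": {"n_pickets": 9, "spacing_mm": 15.0}}
        path = tmp_path / "fi.json"
        path.write_text(json.dumps(doc))
        _assert_plans_equal(load_field_instructions(path),
                            build_picketfence_plan(PicketFenceSpec(9, 15.0)))

    def test_empty_beams_is_schema_error(self, tmp_path):
        path = tmp_path / "fi.json"
        path.write_text(json.dumps({"test_type": "open", "beams": []}))
        with pytest.raises(SchemaError, match="beams"):
            load_field_instructions(path)

    def test_unknown_test_type_names_key(self, tmp_path):
        path = tmp_path / "fi.json"
        path.write_text(json.dumps({"test_type": "sorcery"}))
        with pytest.raises(SchemaError, match="test_type"):
            load_field_instructions(path)

    def test_explicit_leaf_table_reproduced_exactly(self, tmp_path):
        mlc_a = [-20.0] * 60
        mlc_b = [20.0] * 60
        doc = {
            "test_type": "open",
            "beams": [{
                "name": "B1",
                "control_points": [
                    {"meterset_weight": 0.0, "jaws": [-50, 50, -50, 50], "mlc_a": mlc_a, "mlc_b": mlc_b},
                    {"meterset_weight": 1.0, "jaws": [-50, 50, -50, 50], "mlc_a": mlc_a, "mlc_b": mlc_b},
                ],
            }],
        }
        path = tmp_path / "fi.json"
        path.write_text(json.dumps(doc))
        plan = load_field_instructions(path)
        np.testing.assert_array_equal(plan.beams[0].control_points[0].mlc_a, mlc_a)
        np.testing.assert_array_equal(plan.beams[0].control_points[1].mlc_b, mlc_b)
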