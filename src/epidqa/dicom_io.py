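"""File surfaces: DICOM RT-Plan, DICOM RT-Image, a plain-grid sidecar
format, and the JSON field-parameter instruction format.

The RT-Plan dialect is deliberately narrow: photon beams only, one MLCX
leaf-boundary table per plan, UIDs generated deterministically from a seed
so emitted files are byte-reproducible.  Builder metadata (expected picket
centers, junction lines, band ROIs, BB layout) rides in a private tag block
that vendor tooling will ignore.

The sidecar format pairs ``<stem>.json`` (geometry header) with
``<stem>.npy`` (the pixel grid) so image fixtures never require DICOM
tooling; the header fields are ``pixel_spacing_mm``, ``sid_mm``, ``sad_mm``,
``cax_pixel`` and ``meta``.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from . import qa_plans
from .core import Beam, ControlPoint, EPIDImage, MLCModel, PlanValidationError, QAPlan, TEST_TYPES

__all__ = [
    "FormatError",
    "MetadataError",
    "UnsupportedBeamError",
    "SchemaError",
    "write_rtplan",
    "read_rtplan",
    "write_epid_image",
    "read_epid_image",
    "load_field_instructions",
]

RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"
RTIMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"
_PRIVATE_GROUP = 0x3261
_PRIVATE_CREATOR = "EPIDQA"
_DATE = "20200101"  # fixed so emitted files are reproducible


class FormatError(ValueError):
    """File is not in a readable format."""


class MetadataError(FormatError):
    """Required geometry metadata is missing."""


class UnsupportedBeamError(FormatError):
    """Plan contains only electron or setup beams (not supported)."""


class SchemaError(ValueError):
    """JSON field instructions violate the schema."""


def _uid(seed: int, *tags: str) -> str:
    h = hashlib.sha256(("|".join(map(str, (seed,) + tags))).encode()).hexdigest()
    return "2.25." + str(int(h[:30], 16))


def _base_dataset(sop_class: str, seed: int, kind: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = _uid(seed, kind, "sop")
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = _uid(seed, kind, "study")
    ds.SeriesInstanceUID = _uid(seed, kind, "series")
    ds.PatientName = "QA^EPIDQA"
    ds.PatientID = "EPIDQA"
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.StudyDate = _DATE
    ds.StudyTime = "000000"
    ds.Manufacturer = "epidqa"
    return ds


# --------------------------------------------------------------------------
# RT-Plan


def write_rtplan(plan: QAPlan, path: str | Path, seed: int = 0) -> Path:
    """Serialize a QAPlan to a standards-shaped DICOM RT-Plan file.

    Raises :class:`~epidqa.core.PlanValidationError` (naming the offending
    beam and control point) if the plan invariants do not hold.
    """
    plan.validate()
    path = Path(path)
    ds = _base_dataset(RTPLAN_STORAGE, seed, "rtplan")
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.test_type[:16]
    ds.RTPlanName = plan.test_type
    ds.RTPlanDate = _DATE
    ds.RTPlanTime = "000000"
    ds.RTPlanGeometry = "TREATMENT_DEVICE"

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(plan.beams)
    fg.NumberOfBrachyApplicationSetups = 0
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for bi, beam in enumerate(plan.beams, start=1):
        ref = Dataset()
        ref.ReferencedBeamNumber = bi
        ref.BeamMeterset = beam.mu
        fg.ReferencedBeamSequence.append(ref)

        b = Dataset()
        b.BeamNumber = bi
        b.BeamName = beam.name[:64]
        b.BeamType = "DYNAMIC" if len(beam.control_points) > 2 else "STATIC"
        b.RadiationType = "PHOTON"
        b.TreatmentMachineName = plan.machine_name[:16]
        b.TreatmentDeliveryType = "TREATMENT"
        b.SourceAxisDistance = 1000.0
        b.PrimaryDosimeterUnit = "MU"
        b.NumberOfWedges = 0
        b.NumberOfCompensators = 0
        b.NumberOfBoli = 0
        b.NumberOfBlocks = 0
        b.FinalCumulativeMetersetWeight = 1.0
        b.NumberOfControlPoints = len(beam.control_points)

        bld_x = Dataset()
        bld_x.RTBeamLimitingDeviceType = "ASYMX"
        bld_x.NumberOfLeafJawPairs = 1
        bld_y = Dataset()
        bld_y.RTBeamLimitingDeviceType = "ASYMY"
        bld_y.NumberOfLeafJawPairs = 1
        bld_m = Dataset()
        bld_m.RTBeamLimitingDeviceType = "MLCX"
        bld_m.NumberOfLeafJawPairs = plan.mlc_model.n_pairs
        bld_m.LeafPositionBoundaries = [float(v) for v in plan.mlc_model.boundaries_mm]
        b.BeamLimitingDeviceSequence = [bld_x, bld_y, bld_m]

        b.ControlPointSequence = []
        for ci, cp in enumerate(beam.control_points):
            c = Dataset()
            c.ControlPointIndex = ci
            c.CumulativeMetersetWeight = cp.meterset_weight
            c.GantryAngle = cp.gantry_deg
            c.GantryRotationDirection = "NONE"
            c.BeamLimitingDeviceAngle = cp.collimator_deg
            c.PatientSupportAngle = cp.couch_deg
            if ci == 0:
                c.NominalBeamEnergy = _energy_mv(plan.energy)
                c.DoseRateSet = 600
            pos_seq = []
            for dev_type, values in (
                ("ASYMX", [cp.jaws[0], cp.jaws[1]]),
                ("ASYMY", [cp.jaws[2], cp.jaws[3]]),
            ):
                p = Dataset()
                p.RTBeamLimitingDeviceType = dev_type
                p.LeafJawPositions = [float(v) for v in values]
                pos_seq.append(p)
            if cp.mlc_a is not None:
                p = Dataset()
                p.RTBeamLimitingDeviceType = "MLCX"
                p.LeafJawPositions = [float(v) for v in np.concatenate([cp.mlc_a, cp.mlc_b])]
                pos_seq.append(p)
            c.BeamLimitingDevicePositionSequence = pos_seq
            b.ControlPointSequence.append(c)
        ds.BeamSequence.append(b)

    block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR, create=True)
    payload = {
        "test_type": plan.test_type,
        "energy": plan.energy,
        "machine_name": plan.machine_name,
        "mlc_name": plan.mlc_model.name,
        "metadata": plan.metadata,
    }
    block.add_new(0x01, "UT", json.dumps(payload, sort_keys=True))
    ds.save_as(path, enforce_file_format=True)
    return path


def _energy_mv(label: str) -> float:
    digits = "".join(ch for ch in label if ch.isdigit() or ch == ".")
    return float(digits) if digits else 6.0


def read_rtplan(path: str | Path) -> QAPlan:
    """Reconstruct a QAPlan from a DICOM RT-Plan with photon beams."""
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001 - surface as our format error
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    if "BeamSequence" not in ds or len(ds.BeamSequence) == 0:
        raise FormatError("file has no BeamSequence")

    payload = {}
    try:
        block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR)
        payload = json.loads(block[0x01].value)
    except KeyError:
        pass

    mlc_model = None
    mu_by_number = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(fg, "ReferencedBeamSequence", []):
            mu_by_number[int(ref.ReferencedBeamNumber)] = float(ref.BeamMeterset)

    beams = []
    skipped = 0
    for b in ds.BeamSequence:
        if getattr(b, "RadiationType", "PHOTON") != "PHOTON" or \
                getattr(b, "TreatmentDeliveryType", "TREATMENT") == "SETUP":
            skipped += 1
            continue
        for bld in getattr(b, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType.startswith("MLC"):
                mlc_model = MLCModel(
                    name=payload.get("mlc_name", "MLC"),
                    boundaries_mm=np.asarray(bld.LeafPositionBoundaries, dtype=float),
                )
        cps = []
        jaws = (-200.0, 200.0, -200.0, 200.0)
        mlc_a = mlc_b = None
        gantry = coll = couch = 0.0
        for c in b.ControlPointSequence:
            gantry = float(getattr(c, "GantryAngle", gantry))
            coll = float(getattr(c, "BeamLimitingDeviceAngle", coll))
            couch = float(getattr(c, "PatientSupportAngle", couch))
            for p in getattr(c, "BeamLimitingDevicePositionSequence", []):
                vals = np.asarray(p.LeafJawPositions, dtype=float)
                t = p.RTBeamLimitingDeviceType
                if t in ("X", "ASYMX"):
                    jaws = (vals[0], vals[1], jaws[2], jaws[3])
                elif t in ("Y", "ASYMY"):
                    jaws = (jaws[0], jaws[1], vals[0], vals[1])
                elif t.startswith("MLC"):
                    half = vals.size // 2
                    mlc_a, mlc_b = vals[:half].copy(), vals[half:].copy()
            cps.append(
                ControlPoint(
                    meterset_weight=float(c.CumulativeMetersetWeight),
                    gantry_deg=gantry % 360.0,
                    collimator_deg=coll % 360.0,
                    couch_deg=couch % 360.0,
                    jaws=tuple(float(v) for v in jaws),
                    mlc_a=None if mlc_a is None else mlc_a.copy(),
                    mlc_b=None if mlc_b is None else mlc_b.copy(),
                )
            )
        beams.append(Beam(name=str(getattr(b, "BeamName", f"B{b.BeamNumber}")),
                          control_points=cps,
                          mu=mu_by_number.get(int(b.BeamNumber), 100.0)))
    if not beams:
        raise UnsupportedBeamError("plan contains no photon treatment beams")

    test_type = payload.get("test_type", str(getattr(ds, "RTPlanName", "")))
    if test_type not in TEST_TYPES:
        warnings.warn(f"unknown test_type '{test_type}'; treating plan as 'open'", stacklevel=2)
        test_type = "open"
    plan = QAPlan(
        test_type=test_type,
        beams=beams,
        machine_name=payload.get("machine_name", str(beams and getattr(ds.BeamSequence[0], "TreatmentMachineName", "LINAC1"))),
        energy=payload.get("energy", "6X"),
        mlc_model=mlc_model or qa_plans.millennium_120(),
        metadata=payload.get("metadata", {}),
    )
    plan.validate()
    return plan


# --------------------------------------------------------------------------
# EPID images


def write_epid_image(image: EPIDImage, path: str | Path, seed: int = 0) -> Path:
    """Write an EPID image as DICOM RT-Image (``.dcm``) or sidecar (``.json``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _write_sidecar(image, path)
    ds = _base_dataset(RTIMAGE_STORAGE, seed, "rtimage")
    ds.Modality = "RTIMAGE"
    ds.ImageType = ["DERIVED", "SECONDARY", "PORTAL"]
    ds.RTImageLabel = str(image.meta.get("test_type", "EPID"))[:16]
    ds.RTImagePlane = "NORMAL"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = image.pixels.shape
    ds.ImagePlanePixelSpacing = [float(image.pixel_spacing_mm[0]), float(image.pixel_spacing_mm[1])]
    ds.RTImageSID = float(image.sid_mm)
    ds.RadiationMachineSAD = float(image.sad_mm)
    ds.GantryAngle = float(image.meta.get("gantry_deg", 0.0))
    peak = float(image.pixels.max())
    slope = peak / 65535.0 if peak > 0 else 1.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = 0.0
    ds.RescaleType = "US"
    ds.PixelData = np.round(image.pixels / slope).astype(np.uint16).tobytes()
    block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR, create=True)
    block.add_new(0x01, "UT", json.dumps({"cax_pixel": list(image.cax_pixel), "meta": image.meta},
                                         sort_keys=True))
    ds.save_as(path, enforce_file_format=True)
    return path


def _write_sidecar(image: EPIDImage, header_path: Path) -> Path:
    array_path = header_path.with_suffix(".npy")
    np.save(array_path, image.pixels.astype(np.float64))
    header = {
        "format": "epidqa-grid/1",
        "array": array_path.name,
        "pixel_spacing_mm": list(image.pixel_spacing_mm),
        "sid_mm": image.sid_mm,
        "sad_mm": image.sad_mm,
        "cax_pixel": list(image.cax_pixel),
        "meta": image.meta,
    }
    header_path.write_text(json.dumps(header, indent=1, sort_keys=True))
    return header_path


def read_epid_image(path: str | Path) -> EPIDImage:
    """Read DICOM RT-Image or the sidecar grid format into an EPIDImage.

    Missing SID/SAD default to 1000 mm and are flagged in ``meta``; missing
    pixel spacing is a :class:`MetadataError`.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_sidecar(path)
    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise MetadataError("image has no pixel spacing")
    meta = {}
    sid = getattr(ds, "RTImageSID", None)
    sad = getattr(ds, "RadiationMachineSAD", None)
    if sid is None:
        sid, meta["sid_defaulted"] = 1000.0, True
    if sad is None:
        sad, meta["sad_defaulted"] = 1000.0, True
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = ds.pixel_array.astype(float) * slope + intercept
    cax = None
    try:
        block = ds.private_block(_PRIVATE_GROUP, _PRIVATE_CREATOR)
        extra = json.loads(block[0x01].value)
        cax = tuple(extra.get("cax_pixel")) if extra.get("cax_pixel") else None
        meta.update(extra.get("meta", {}))
    except KeyError:
        pass
    meta.setdefault("gantry_deg", float(getattr(ds, "GantryAngle", 0.0)))
    return EPIDImage(
        pixels=pixels,
        pixel_spacing_mm=(float(spacing[0]), float(spacing[1])),
        sid_mm=float(sid),
        sad_mm=float(sad),
        cax_pixel=cax,
        meta=meta,
    )


def _read_sidecar(header_path: Path) -> EPIDImage:
    try:
        header = json.loads(header_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar header is not valid JSON: {exc}") from exc
    if header.get("format") != "epidqa-grid/1":
        raise FormatError("not an epidqa-grid/1 sidecar header")
    if "pixel_spacing_mm" not in header:
        raise MetadataError("sidecar header has no pixel spacing")
    pixels = np.load(header_path.parent / header["array"])
    return EPIDImage(
        pixels=pixels,
        pixel_spacing_mm=tuple(header["pixel_spacing_mm"]),
        sid_mm=float(header.get("sid_mm", 1000.0)),
        sad_mm=float(header.get("sad_mm", 1000.0)),
        cax_pixel=tuple(header["cax_pixel"]) if header.get("cax_pixel") else None,
        meta=dict(header.get("meta", {})),
    )


# --------------------------------------------------------------------------
# JSON field instructions


def load_field_instructions(path: str | Path) -> QAPlan:
    """Build a QAPlan from a JSON field-parameter instruction file.

    The document gives either a parametric descriptor (``test_type`` plus
    ``params`` forwarded to the matching builder) or explicit ``beams``
    tables; see ``docs/field-instructions.md`` for the schema.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"instructions are not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("top-level document must be an object")
    test_type = doc.get("test_type")
    if test_type not in TEST_TYPES:
        raise SchemaError(f"'test_type' missing or unknown: {test_type!r}")
    common = {
        "energy": doc.get("energy", "6X"),
        "machine_name": doc.get("machine_name", "LINAC1"),
    }
    if "beams" in doc:
        return _plan_from_beam_tables(doc, test_type, common)
    params = doc.get("params", {})
    if not isinstance(params, dict):
        raise SchemaError("'params' must be an object")
    try:
        return _dispatch_builder(test_type, params, common)
    except TypeError as exc:
        raise SchemaError(f"bad parameter for test '{test_type}': {exc}") from exc
    except PlanValidationError as exc:
        raise SchemaError(f"invalid parameters for test '{test_type}': {exc}") from exc


def _dispatch_builder(test_type: str, params: dict, common: dict) -> QAPlan:
    p = dict(params)
    if test_type == "open":
        fs = p.pop("field_size_mm", (100.0, 100.0))
        return qa_plans.build_open_field_plan(tuple(fs), gantry_deg=p.pop("gantry_deg", 0.0), **common)
    if test_type == "junction":
        return qa_plans.build_junction_plan(
            junction_axes=tuple(p.pop("junction_axes", ("x", "y"))),
            half_size_mm=p.pop("half_size_mm", 60.0),
            junction_error_mm=p.pop("junction_error_mm", 0.0),
            **common,
        )
    if test_type == "lightrad":
        return qa_plans.build_lightrad_plan(
            field_size_mm=tuple(p.pop("field_size_mm", (150.0, 150.0))),
            inner_offset_mm=p.pop("inner_offset_mm", 5.0),
            outer_offset_mm=p.pop("outer_offset_mm", 25.0),
            **common,
        )
    if test_type == "picketfence":
        spec = qa_plans.PicketFenceSpec(
            n_pickets=int(p.pop("n_pickets", 9)),
            spacing_mm=float(p.pop("spacing_mm", 15.0)),
            gap_mm=float(p.pop("gap_mm", 2.0)),
        )
        return qa_plans.build_picketfence_plan(
            spec, leaf_offsets_mm=np.asarray(p.pop("leaf_offsets_mm", 0.0), dtype=float), **common
        )
    if test_type == "dlg":
        return qa_plans.build_dlg_plan(tuple(p.pop("gap_widths_mm", (2.0, 4.0, 6.0, 10.0, 14.0, 16.0, 20.0))), **common)
    if test_type == "winston_lutz":
        combos = p.pop("combos", None)
        combos = None if combos is None else [tuple(c) for c in combos]
        return qa_plans.build_winston_lutz_plan(combos, field_size_mm=p.pop("field_size_mm", 20.0), **common)
    # vmat_t1 / vmat_t2 / vmat_t3
    which = p.pop("which", {"vmat_t1": "t1_static_dmlc", "vmat_t2": "t2_doserate_gantry",
                            "vmat_t3": "t3_mlc_speed"}[test_type])
    return qa_plans.build_vmat_plans(
        which, band_count=p.pop("band_count", None),
        inject_mlc_errors=bool(p.pop("inject_mlc_errors", False)), **common
    )


def _plan_from_beam_tables(doc: dict, test_type: str, common: dict) -> QAPlan:
    beams_doc = doc["beams"]
    if not isinstance(beams_doc, list) or not beams_doc:
        raise SchemaError("'beams' must be a non-empty list")
    beams = []
    for i, b in enumerate(beams_doc):
        cps_doc = b.get("control_points")
        if not cps_doc or len(cps_doc) < 2:
            raise SchemaError(f"beams[{i}].control_points must list >= 2 control points")
        cps = []
        for j, c in enumerate(cps_doc):
            if "meterset_weight" not in c or "jaws" not in c:
                raise SchemaError(f"beams[{i}].control_points[{j}] needs 'meterset_weight' and 'jaws'")
            cps.append(
                ControlPoint(
                    meterset_weight=float(c["meterset_weight"]),
                    gantry_deg=float(c.get("gantry_deg", 0.0)),
                    collimator_deg=float(c.get("collimator_deg", 0.0)),
                    couch_deg=float(c.get("couch_deg", 0.0)),
                    jaws=tuple(float(v) for v in c["jaws"]),
                    mlc_a=np.asarray(c["mlc_a"], dtype=float) if "mlc_a" in c else None,
                    mlc_b=np.asarray(c["mlc_b"], dtype=float) if "mlc_b" in c else None,
                )
            )
        beams.append(Beam(name=str(b.get("name", f"B{i + 1}")), control_points=cps,
                          mu=float(b.get("mu", 100.0))))
    plan = QAPlan(test_type=test_type, beams=beams, metadata=dict(doc.get("metadata", {})), **common)
    try:
        plan.validate()
    except PlanValidationError as exc:
        raise SchemaError(f"beams: {exc}") from exc
    return plan
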