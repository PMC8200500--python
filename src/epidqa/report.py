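"""Tolerance evaluation, JSON reports, contingency tables, and batch
error-injection sweeps.

Default tolerances: junction +/-0.3 (dimensionless), VMAT bands +/-1.5%,
leaf positions 1 mm, light-rad BB deviation 2 mm, gamma pass rate 95% at
3%/3 mm, Winston-Lutz offset 1 mm.  All are overridable through a single
tolerance configuration mapping so institutions can tighten or relax them
without code changes.

For sensitivity, a *failing* test is the positive class: sensitivity is the
percentage of truly failing deliveries that the analyzer also fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import analysis, epid_synth, qa_plans
from .analysis import (
    AnalysisError,
    GammaResult,
    JunctionResult,
    LightRadResult,
    PicketFenceResult,
    VMATBandResult,
    WinstonLutzResult,
)
__all__ = [
    "DEFAULT_TOLERANCES",
    "QAReport",
    "evaluate_tolerances",
    "ContingencyTable",
    "contingency",
    "run_error_sweep",
]

log = logging.getLogger("epidqa")

REPORT_SCHEMA_VERSION = 1

DEFAULT_TOLERANCES = {
    "junction": analysis.JUNCTION_TOLERANCE,
    "band_pct": analysis.BAND_TOLERANCE_PCT,
    "leaf_mm": analysis.LEAF_TOLERANCE_MM,
    "lightrad_mm": analysis.LIGHTRAD_TOLERANCE_MM,
    "gamma_pass_rate_pct": 95.0,
    "winston_lutz_mm": 1.0,
}


@dataclass
class QAReport:
    """Serializable record of one analyzed QA test."""

    test_type: str
    payload: dict
    tolerances: dict
    passed: bool
    machine: str = ""
    date: str = ""
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "schema_version": self.schema_version,
                "test_type": self.test_type,
                "machine": self.machine,
                "date": self.date,
                "tolerances": self.tolerances,
                "passed": self.passed,
                "payload": self.payload,
            },
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "QAReport":
        text = text_or_path
        if isinstance(text_or_path, Path) or (isinstance(text_or_path, str) and "\n" not in text_or_path
                                              and Path(text_or_path).exists()):
            text = Path(text_or_path).read_text()
        doc = json.loads(text)
        return cls(
            test_type=doc["test_type"],
            payload=doc["payload"],
            tolerances=doc["tolerances"],
            passed=doc["passed"],
            machine=doc.get("machine", ""),
            date=doc.get("date", ""),
            schema_version=doc.get("schema_version", REPORT_SCHEMA_VERSION),
        )


def _nan_to_none(arr: np.ndarray) -> list:
    return [[None if not np.isfinite(v) else float(v) for v in row] for row in np.atleast_2d(arr)]


def _payload_of(result) -> tuple[str, dict]:
    if isinstance(result, JunctionResult):
        return "junction", {"junctions": dict(result.junctions), "samples": result.samples}
    if isinstance(result, LightRadResult):
        return "lightrad", {
            "bb_centers_mm": {str(k): list(v) for k, v in result.bb_centers_mm.items()},
            "bb_edge_distance_mm": {str(k): v for k, v in result.bb_edge_distance_mm.items()},
            "deviation_mm": {str(k): v for k, v in result.deviation_mm.items()},
            "undetected": list(result.undetected),
            "field_edges": list(result.field_edges.as_tuple()),
        }
    if isinstance(result, PicketFenceResult):
        return "picketfence", {
            "active_pairs": list(result.active_pairs),
            "expected_mm": _nan_to_none(result.expected_mm),
            "measured_mm": _nan_to_none(result.measured_mm),
        }
    if isinstance(result, VMATBandResult):
        return "vmat_bands", {"r_test": result.r_test.tolist(), "r_open": result.r_open.tolist()}
    if isinstance(result, GammaResult):
        return "gamma", {
            "pass_rate_pct": result.pass_rate_pct,
            "max_gamma": result.max_gamma,
            "dd_pct": result.dd_pct,
            "dta_mm": result.dta_mm,
            "low_dose_cutoff_pct": result.low_dose_cutoff_pct,
        }
    if isinstance(result, WinstonLutzResult):
        return "winston_lutz", {
            "bb_center_mm": list(result.bb_center_mm),
            "field_center_mm": list(result.field_center_mm),
            "offset_vector_mm": list(result.offset_vector_mm),
            "offset_magnitude_mm": result.offset_magnitude_mm,
        }
    raise AnalysisError(f"unknown result type {type(result).__name__}")


def _evaluate_payload(kind: str, payload: dict, tol: dict) -> bool:
    if kind == "junction":
        values = list(payload["junctions"].values())
        return bool(values) and max(abs(v) for v in values) <= tol["junction"]
    if kind == "lightrad":
        dev = payload["deviation_mm"]
        return bool(dev) and all(abs(v) <= tol["lightrad_mm"] for v in dev.values())
    if kind == "picketfence":
        exp = np.array([[np.nan if v is None else v for v in row] for row in payload["expected_mm"]])
        mea = np.array([[np.nan if v is None else v for v in row] for row in payload["measured_mm"]])
        det = np.isfinite(mea)
        if not det.any():
            return False
        return bool(np.all(np.abs((exp - mea)[det]) <= tol["leaf_mm"]))
    if kind == "vmat_bands":
        c = np.asarray(payload["r_test"], dtype=float) / np.asarray(payload["r_open"], dtype=float)
        pd = 100.0 * (c / c.mean() - 1.0)
        return bool(np.all(np.abs(pd) <= tol["band_pct"]))
    if kind == "gamma":
        return payload["pass_rate_pct"] >= tol["gamma_pass_rate_pct"]
    if kind == "winston_lutz":
        return payload["offset_magnitude_mm"] <= tol["winston_lutz_mm"]
    raise AnalysisError(f"unknown report payload kind '{kind}'")


def evaluate_tolerances(result, tolerance_config: dict | None = None,
                        machine: str = "", date: str = "") -> QAReport:
    """Apply (possibly overridden) tolerances to a result and build a report.

    Accepts either a fresh analyzer result or an existing :class:`QAReport`
    (re-evaluation is idempotent: pass flags are recomputed from the stored
    measurements, never trusted).
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerance_config:
        unknown = set(tolerance_config) - set(tol)
        if unknown:
            raise AnalysisError(f"unknown tolerance keys: {sorted(unknown)}")
        tol.update(tolerance_config)
    if isinstance(result, QAReport):
        kind, payload = result.test_type, result.payload
        machine = machine or result.machine
        date = date or result.date
    else:
        kind, payload = _payload_of(result)
    passed = _evaluate_payload(kind, payload, tol)
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
    log.info("evaluated %s report (payload %s): %s", kind, digest, "PASS" if passed else "FAIL")
    return QAReport(test_type=kind, payload=payload, tolerances=tol, passed=passed,
                    machine=machine, date=date)


# --------------------------------------------------------------------------
# contingency / sensitivity


@dataclass
class ContingencyTable:
    """2x2 pass/fail counts between a reference (truth) and a measurement.

    Failing is the positive class; ``fail_fail`` counts true failures the
    analyzer caught (true positives).
    """

    pass_pass: int = 0
    pass_fail: int = 0  # truth passed, measured failed (false positive)
    fail_pass: int = 0  # truth failed, measured passed (miss)
    fail_fail: int = 0

    @property
    def sensitivity_pct(self) -> float:
        positives = self.fail_fail + self.fail_pass
        if positives == 0:
            raise AnalysisError("no failing cases in the reference: sensitivity undefined")
        return 100.0 * self.fail_fail / positives

    def to_dict(self) -> dict:
        d = {
            "pass_pass": self.pass_pass,
            "pass_fail": self.pass_fail,
            "fail_pass": self.fail_pass,
            "fail_fail": self.fail_fail,
        }
        try:
            d["sensitivity_pct"] = self.sensitivity_pct
        except AnalysisError:
            d["sensitivity_pct"] = None
        return d


def contingency(results_truth: list[bool], results_measured: list[bool]) -> ContingencyTable:
    """Build the 2x2 table from paired pass(True)/fail(False) lists."""
    if not results_truth or len(results_truth) != len(results_measured):
        raise AnalysisError("need equal-length, non-empty paired pass/fail lists")
    table = ContingencyTable()
    for t, m in zip(results_truth, results_measured):
        if t and m:
            table.pass_pass += 1
        elif t and not m:
            table.pass_fail += 1
        elif not t and m:
            table.fail_pass += 1
        else:
            table.fail_fail += 1
    return table


# --------------------------------------------------------------------------
# batch error-injection sweep


JUNCTION_ERRORS_MM = (-4.0, -2.0, 0.0, 2.0, 4.0)  # negative = overlap
LIGHTRAD_SSDS_MM = (950.0, 975.0, 990.0, 1000.0, 1010.0, 1025.0, 1050.0)


def _junction_truth(error_mm: float, config: epid_synth.RenderConfig,
                    tol: float) -> bool:
    """Analytic pass/fail for an injected jaw gap/overlap (erf edge model).

    At the match line two complementary erf edges displaced by the error sum
    to ``1 -/+ erf(|e|/2 / (sigma sqrt 2))`` of the plateau, so the expected
    junction value is ``-/+ erf(...)`` for gaps/overlaps.
    """
    from scipy.special import erf as _erf

    magnitude = _erf(abs(error_mm) / 2.0 / (config.penumbra_sigma_mm * np.sqrt(2.0)))
    return bool(magnitude <= tol)


def _lightrad_truth(ssd_mm: float, inner_mm: float, half_mm: float, sad_mm: float,
                    tol: float) -> bool:
    """Projection-oracle pass/fail for a phantom set up at the wrong SSD."""
    projected = (half_mm - inner_mm) * sad_mm / ssd_mm
    deviation = (half_mm - projected) - inner_mm
    return bool(abs(deviation) <= tol)


def run_error_sweep(seed: int = 0, noise_sigma: float = 0.0,
                    config: epid_synth.RenderConfig | None = None) -> dict:
    """Render and analyze the full error-injection protocol; tabulate contingency.

    Junction gaps/overlaps of 0, +/-2, +/-4 mm and light-rad phantom SSDs of
    95-105 cm are injected; ground truth comes from the closed-form edge and
    projection oracles at the default tolerances.  Returns per-test
    contingency tables plus the individual case records.
    """
    config = config or epid_synth.RenderConfig()
    cases = []
    truth, measured = [], []
    for i, err in enumerate(JUNCTION_ERRORS_MM):
        plan = qa_plans.build_junction_plan(junction_error_mm=err)
        em = epid_synth.ErrorModel(noise_sigma=noise_sigma, seed=seed + i)
        image = epid_synth.render_junction_image(plan, config, em)
        result = analysis.analyze_junction(image, plan)
        truth.append(_junction_truth(err, config, analysis.JUNCTION_TOLERANCE))
        measured.append(result.passed)
        cases.append({"test": "junction", "error_mm": err, "worst_value": result.worst_value,
                      "truth_pass": truth[-1], "measured_pass": measured[-1]})
    junction_table = contingency(truth, measured)

    truth, measured = [], []
    plan = qa_plans.build_lightrad_plan()
    half = plan.metadata["field_size_mm"][0] / 2.0
    inner = plan.metadata["inner_offset_mm"]
    for i, ssd in enumerate(LIGHTRAD_SSDS_MM):
        em = epid_synth.ErrorModel(ssd_mm=ssd, noise_sigma=noise_sigma, seed=seed + 100 + i)
        image = epid_synth.render_lightrad_image(plan, config, em)
        result = analysis.analyze_lightrad(image, plan)
        truth.append(_lightrad_truth(ssd, inner, half, config.sad_mm,
                                     analysis.LIGHTRAD_TOLERANCE_MM))
        measured.append(result.passed)
        dev = max((abs(v) for v in result.deviation_mm.values()), default=None)
        cases.append({"test": "lightrad", "ssd_mm": ssd, "max_abs_deviation_mm": dev,
                      "truth_pass": truth[-1], "measured_pass": measured[-1]})
    lightrad_table = contingency(truth, measured)

    return {
        "junction": junction_table.to_dict(),
        "lightrad": lightrad_table.to_dict(),
        "cases": cases,
    }
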