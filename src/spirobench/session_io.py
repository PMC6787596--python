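"""File formats and session records.

Trace CSV dialect (UTF-8, '.' decimal, diff-able and spreadsheet friendly)::

    # spirobench-trace v1
    # sample_rate_hz: 100.0
    # calibration: default
    # annotation: tidal,0.000,60.000
    # annotation: rest,60.000,65.000
    t_s,v_pressure_a,v_pressure_b,v_gas_no,v_gas_co
    0.000000,0.200049,0.200049,0.600195,0.600195
    ...

Columns may appear in any order; comment lines carry the sample rate, a
calibration reference and the segment annotations. Readers reject missing
columns, nonuniform timestamps (1% of the sample period) and NaN runs longer
than 0.5 s, reporting the offending line.

Calibration profiles round-trip through YAML, field-for-field with
:class:`~spirobench.device_model.SensorCalibration`.
"""

from __future__ import annotations

import io
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .device_model import SensorCalibration, default_calibration
from .errors import TraceFormatError
from .simulate import Annotation, GroundTruth, RawTrace

__all__ = [
    "TRACE_COLUMNS",
    "write_trace_csv",
    "read_trace_csv",
    "save_calibration",
    "load_calibration",
    "SessionRecord",
    "SubjectInfo",
    "metrics_to_json_dict",
    "ground_truth_to_dict",
    "RESULT_UNITS",
]

TRACE_COLUMNS = ("t_s", "v_pressure_a", "v_pressure_b", "v_gas_no", "v_gas_co")

#: units of every numeric field emitted in result JSON documents
RESULT_UNITS = {
    "fev1": "L",
    "fvc": "L",
    "pef": "L/s",
    "fev1_fvc_ratio": "dimensionless",
    "fet": "s",
    "bev": "L",
    "t0": "s",
    "mean_conc_ppm": "ppm",
    "mean_conc_ppb": "ppb",
    "sd_conc_ppm": "ppm",
    "below_floor_fraction": "fraction",
    "bias": "metric units",
    "loa_low": "metric units",
    "loa_high": "metric units",
    "pearson_r": "dimensionless",
    "pearson_p": "probability",
}


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def write_trace_csv(
    trace: RawTrace,
    path: str | Path,
    calibration_ref: str = "default",
    precision: int = 6,
) -> None:
    """Write a RawTrace in the v1 dialect (lossless at the declared precision)."""
    path = Path(path)
    fmt = f"%.{precision}f"
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# spirobench-trace v1\n")
        fh.write(f"# sample_rate_hz: {trace.sample_rate!r}\n")
        fh.write(f"# calibration: {calibration_ref}\n")
        for ann in trace.annotations:
            fh.write(f"# annotation: {ann.label},{ann.start_s:.3f},{ann.end_s:.3f}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        data = np.column_stack([
            trace.t, trace.v_pressure_a, trace.v_pressure_b,
            trace.v_gas_no, trace.v_gas_co,
        ])
        np.savetxt(fh, data, fmt=fmt, delimiter=",")


def read_trace_csv(path: str | Path) -> tuple[RawTrace, str]:
    """Parse a v1 trace file; returns ``(trace, calibration_ref)``.

    Raises :class:`TraceFormatError` (with a line number where possible) on a
    missing column, nonuniform timestamps or NaN runs longer than 0.5 s.
    """
    path = Path(path)
    sample_rate: Optional[float] = None
    calibration_ref = "default"
    annotations: list[Annotation] = []
    header_line = None
    data_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("sample_rate_hz:"):
                    sample_rate = float(body.split(":", 1)[1])
                elif body.startswith("calibration:"):
                    calibration_ref = body.split(":", 1)[1].strip()
                elif body.startswith("annotation:"):
                    try:
                        label, s0, s1 = body.split(":", 1)[1].strip().split(",")
                        annotations.append(Annotation(label.strip(), float(s0), float(s1)))
                    except ValueError:
                        raise TraceFormatError("malformed annotation comment", lineno)
                continue
            if header_line is None:
                header_line = (lineno, line)
            else:
                data_lines.append(line)
    if header_line is None:
        raise TraceFormatError("no header row found")
    header_lineno, header = header_line
    columns = [c.strip() for c in header.split(",")]
    missing = [c for c in TRACE_COLUMNS if c not in columns]
    if missing:
        raise TraceFormatError(f"missing column(s): {missing}", header_lineno)

    df = pd.read_csv(io.StringIO("\n".join([header] + data_lines)))
    if len(df) < 2:
        raise TraceFormatError("trace needs at least 2 samples")
    t = df["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    period = float(np.median(dt))
    if period <= 0:
        raise TraceFormatError("timestamps not strictly increasing")
    bad = np.nonzero(np.abs(dt - period) > 0.01 * period)[0]
    if bad.size:
        i = int(bad[0])
        raise TraceFormatError(
            f"nonuniform sampling at t={t[i + 1]:.6f} s "
            f"(step {dt[i]:.6f} s vs period {period:.6f} s)",
            header_lineno + 1 + i + 1,
        )
    if sample_rate is None:
        sample_rate = 1.0 / period
    elif abs(1.0 / period - sample_rate) > 0.01 * sample_rate:
        raise TraceFormatError(
            f"declared sample rate {sample_rate} Hz inconsistent with data "
            f"period {period:.6f} s"
        )

    max_nan_run = int(math.ceil(0.5 * sample_rate))
    channels = {}
    for col in TRACE_COLUMNS[1:]:
        x = df[col].to_numpy(dtype=float)
        isnan = np.isnan(x)
        if isnan.any():
            run = 0
            for i, flag in enumerate(isnan):
                run = run + 1 if flag else 0
                if run > max_nan_run:
                    raise TraceFormatError(
                        f"NaN run longer than 0.5 s in column {col}",
                        header_lineno + 1 + i + 1,
                    )
            # short gaps are bridged by linear interpolation
            x = np.interp(np.arange(len(x)), np.nonzero(~isnan)[0], x[~isnan])
        channels[col] = x

    trace = RawTrace(
        sample_rate=float(sample_rate),
        t=t,
        v_pressure_a=channels["v_pressure_a"],
        v_pressure_b=channels["v_pressure_b"],
        v_gas_no=channels["v_gas_no"],
        v_gas_co=channels["v_gas_co"],
        annotations=annotations,
    )
    return trace, calibration_ref


# ---------------------------------------------------------------------------
# calibration YAML
# ---------------------------------------------------------------------------

def save_calibration(cal: SensorCalibration, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(cal.to_dict(), fh, sort_keys=False)


def load_calibration(path: str | Path | None) -> SensorCalibration:
    """Load a calibration profile; None or "default" yields the shipped profile."""
    if path is None or str(path) == "default":
        return default_calibration()
    with Path(path).open("r", encoding="utf-8") as fh:
        return SensorCalibration.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# session metadata record
# ---------------------------------------------------------------------------

class SubjectInfo(BaseModel):
    id: str
    group: str = "control"
    age_years: float | None = Field(default=None, ge=0, le=120)
    sex: str | None = None
    height_cm: float | None = Field(default=None, gt=0)


class SessionRecord(BaseModel):
    """Validated session metadata (GPS tagging only; no geospatial math)."""

    session_id: str
    timestamp: str
    gps: tuple[float, float] | None = None
    subject: SubjectInfo
    device_profile: str = "default"
    trace_file: str | None = None

    @field_validator("gps")
    @classmethod
    def _check_gps(cls, v):
        if v is None:
            return v
        lat, lon = v
        if not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude {lat} outside [-90, 90]")
        if not (-180.0 <= lon <= 180.0):
            raise ValueError(f"longitude {lon} outside [-180, 180]")
        return v


# ---------------------------------------------------------------------------
# JSON result documents
# ---------------------------------------------------------------------------

def metrics_to_json_dict(analysis) -> dict:
    """Serialise a SessionAnalysis to a JSON-ready dict with units attached."""
    from .spiro_analysis import SessionAnalysis  # local import to avoid cycle

    assert isinstance(analysis, SessionAnalysis)
    doc = {
        "units": {k: RESULT_UNITS[k] for k in
                  ("fev1", "fvc", "pef", "fev1_fvc_ratio", "fet", "bev", "t0")},
        "maneuvers": [],
    }
    for res in analysis.maneuvers:
        m = res.metrics
        doc["maneuvers"].append({
            "fev1": m.fev1, "fvc": m.fvc, "pef": m.pef,
            "fev1_fvc_ratio": m.fev1_fvc_ratio, "fet": m.fet,
            "bev": m.bev, "t0": m.t0,
            "flags": {"bev_ok": res.flags.bev_ok, "fet_ok": res.flags.fet_ok,
                      "end_of_test_ok": res.flags.end_of_test_ok,
                      "extended_grading": True},
            "flagged_sample_fraction": res.flagged_sample_fraction,
        })
    if analysis.report is not None:
        r = analysis.report
        doc["session"] = {
            "repeatable_fev1": r.session_repeatable_fev1,
            "repeatable_fvc": r.session_repeatable_fvc,
            "n_acceptable": r.n_acceptable,
            "best": {"fev1": r.best.fev1, "fvc": r.best.fvc, "pef": r.best.pef,
                     "fev1_fvc_ratio": r.best.fev1_fvc_ratio},
        }
    return doc


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "subject_group": truth.subject_group,
        "gas_no_ppb": truth.gas_no_ppb,
        "gas_co_ppm": truth.gas_co_ppm,
        "maneuvers": [t._asdict() for t in truth.maneuvers],
    }


def write_json(doc: dict, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")
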