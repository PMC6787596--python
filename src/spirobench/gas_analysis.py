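"""Exhaled NO and CO quantification from the tidal-breathing window.

Breath-gas readings are taken during the 60 s of tidal breathing that precedes
the forced maneuvers — the ordering matters physiologically, because a forced
expiration transiently depresses exhaled NO, so any gas window that follows a
maneuver is flagged as protocol-violating. The first seconds of the window are
discarded to let the electrochemical cells equilibrate, then the retained
samples are summarised by their mean and SD. NO is reported in ppb
(1000 × ppm); physiologic reference ranges are 0.03–0.13 ppm for NO and
2–7 ppm for CO.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .device_model import GasSensorSpec, SensorCalibration, gas_voltage_to_concentration
from .errors import CalibrationError, GasQuantificationError
from .simulate import Annotation, RawTrace

__all__ = [
    "GasReading",
    "PHYSIOLOGIC_RANGE_PPM",
    "summarize_gas_window",
    "calibrate_gas_sensor",
    "sequence_check",
    "analyze_session_gas",
    "EQUILIBRATION_DISCARD_S",
]

#: physiologic exhaled ranges in asthma, ppm
PHYSIOLOGIC_RANGE_PPM = {"NO": (0.03, 0.13), "CO": (2.0, 7.0)}

#: default equilibration discard at the start of the tidal window (s)
EQUILIBRATION_DISCARD_S = 10.0


@dataclass(frozen=True)
class GasReading:
    """Windowed breath-gas estimate with calibration provenance."""

    analyte: str
    mean_conc_ppm: float
    sd_conc_ppm: float
    window: tuple[float, float]  # (start_s, end_s) of the retained samples
    n_samples: int
    below_floor_fraction: float
    in_physiologic_range: bool
    protocol_violation: bool = False

    @property
    def mean_conc_ppb(self) -> float:
        return 1000.0 * self.mean_conc_ppm

    @property
    def reliable(self) -> bool:
        """Usable for cohort summaries: in-protocol and mostly above floor."""
        return not self.protocol_violation and self.below_floor_fraction < 0.5


def summarize_gas_window(
    conc_ppm: np.ndarray,
    sample_rate: float,
    window: tuple[float, float],
    spec: GasSensorSpec,
    phys_range: tuple[float, float] | None = None,
    equilibration_discard_s: float = EQUILIBRATION_DISCARD_S,
) -> GasReading:
    """Summarise one analyte over a time window of a concentration series.

    The first ``equilibration_discard_s`` seconds of the window are dropped
    (electrochemical cells approach their steady reading over seconds), then
    the mean and SD of the retained samples are reported along with the
    fraction below the calibrated detection floor and a physiologic-range flag.
    """
    conc_ppm = np.asarray(conc_ppm, dtype=float)
    start_s, end_s = window
    if end_s - start_s < 10.0:
        raise GasQuantificationError(
            f"gas window of {end_s - start_s:.1f} s is too short (need >= 10 s)"
        )
    if phys_range is None:
        phys_range = PHYSIOLOGIC_RANGE_PPM[spec.analyte]
    i0 = int(round((start_s + equilibration_discard_s) * sample_rate))
    i1 = int(round(end_s * sample_rate))
    i0 = min(i0, len(conc_ppm))
    i1 = min(i1, len(conc_ppm))
    retained = conc_ppm[i0:i1]
    if retained.size < 2:
        raise GasQuantificationError("no samples left after equilibration discard")
    mean = float(retained.mean())
    return GasReading(
        analyte=spec.analyte,
        mean_conc_ppm=mean,
        sd_conc_ppm=float(retained.std(ddof=1)),
        window=(start_s + equilibration_discard_s, end_s),
        n_samples=int(retained.size),
        below_floor_fraction=float(np.mean(retained < spec.detection_floor)),
        in_physiologic_range=bool(phys_range[0] <= mean <= phys_range[1]),
    )


def calibrate_gas_sensor(
    known_conc_ppm,
    measured_volts,
    spec: GasSensorSpec,
    r2_min: float = 0.99,
) -> tuple[GasSensorSpec, float]:
    """Least-squares line fit of voltage against known concentration.

    Returns the updated spec (new sensitivity and baseline) and the residual
    RMS in volts. A fit with R² below ``r2_min`` is rejected: a sensor that
    nonlinear should not be trusted with a two-constant calibration.
    """
    c = np.asarray(known_conc_ppm, dtype=float)
    v = np.asarray(measured_volts, dtype=float)
    if c.size != v.size:
        raise CalibrationError("concentration and voltage lists differ in length")
    if np.unique(c).size < 2:
        raise CalibrationError("need >= 2 distinct concentrations to calibrate")
    res = stats.linregress(c, v)
    if res.slope <= 0:
        raise CalibrationError(f"non-positive fitted sensitivity {res.slope:.3g} V/ppm")
    predicted = res.intercept + res.slope * c
    rms = float(np.sqrt(np.mean((v - predicted) ** 2)))
    r2 = float(res.rvalue**2)
    if r2 < r2_min:
        raise CalibrationError(
            f"calibration fit R²={r2:.4f} below {r2_min}: sensor response nonlinear"
        )
    updated = replace(spec, sensitivity=float(res.slope), v_baseline=float(res.intercept))
    return updated, rms


def sequence_check(
    annotations: list[Annotation],
    gas_window: tuple[float, float] | None = None,
) -> bool:
    """True when the gas window violates protocol order (after a maneuver).

    Spirometry transiently depresses exhaled NO, so gas quantification must
    precede the forced maneuvers; a window starting after any maneuver onset
    makes the NO estimate unreliable.
    """
    if gas_window is None:
        tidal = [a for a in annotations if a.label == "tidal"]
        if not tidal:
            return False
        gas_window = (tidal[0].start_s, tidal[0].end_s)
    maneuvers = [a for a in annotations if a.label == "maneuver"]
    return any(gas_window[0] >= m.start_s for m in maneuvers)


def analyze_session_gas(
    trace: RawTrace,
    cal: SensorCalibration,
    equilibration_discard_s: float = EQUILIBRATION_DISCARD_S,
) -> dict[str, GasReading]:
    """NO and CO readings for one session, from its tidal-breathing window."""
    tidal = trace.segments("tidal")
    if not tidal:
        raise GasQuantificationError("session has no annotated tidal window")
    window = (tidal[0].start_s, tidal[0].end_s)
    violation = sequence_check(trace.annotations, window)
    out: dict[str, GasReading] = {}
    for analyte, volts, spec in (
        ("NO", trace.v_gas_no, cal.gas_no),
        ("CO", trace.v_gas_co, cal.gas_co),
    ):
        conc, _ = gas_voltage_to_concentration(volts, spec)
        reading = summarize_gas_window(
            conc, trace.sample_rate, window, spec,
            equilibration_discard_s=equilibration_discard_s,
        )
        out[analyte] = replace(reading, protocol_violation=violation)
    return out
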