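"""Flow reconstruction and spirometry metrics.

Given a raw voltage trace and a device calibration this module rebuilds the
exhaled flow (offset correction → per-sensor inversion → dual-range fusion),
integrates it to volume, corrects the maneuver start time by back-extrapolation
(tangent to the volume–time curve at peak flow), and computes the standard
forced expiratory metrics:

* FEV1 — volume delivered in the first second of the maneuver, timed from the
  back-extrapolated time zero t0;
* FVC — total volume delivered by a maximally forceful, complete expiration;
* PEF — peak expiratory flow; FET — forced expiratory time; BEV — volume
  already expired before t0 (a maneuver-quality indicator).

Maneuvers are graded with the usual acceptability conventions (BEV below
max(0.150 L, 5% FVC); expiration of at least six seconds; an end-of-test
plateau of < 0.025 L volume change over one second) and sessions with the
repeatability rule that the two largest FEV1 and FVC values agree within
0.150 L. Only the 0.150 L repeatability rule is part of the device's own
recording convention; the per-maneuver flags are extended grading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .device_model import SensorCalibration, fuse_dual_sensors, voltage_to_flow
from .errors import GradingUnavailableError, MetricError, UnsupportedDemographicsError
from .simulate import Annotation, RawTrace

__all__ = [
    "SpirometryMetrics",
    "ManeuverFlags",
    "AcceptabilityReport",
    "FlowVolumeLoop",
    "ChannelOffsets",
    "ManeuverResult",
    "SessionAnalysis",
    "estimate_zero_offset",
    "reconstruct_flow",
    "integrate_volume",
    "detect_time_zero",
    "end_of_test",
    "compute_metrics",
    "grade_session",
    "flow_volume_loop",
    "analyze_maneuver",
    "analyze_session",
    "percent_predicted",
    "ReferenceEquationRegistry",
    "EOT_PLATEAU_LITERS",
    "REPEATABILITY_LITERS",
]

#: end-of-test plateau criterion: volume change over a trailing 1-s window (L)
EOT_PLATEAU_LITERS = 0.025
EOT_WINDOW_S = 1.0
#: repeatability: two largest FEV1 (and FVC) must agree within this (L)
REPEATABILITY_LITERS = 0.150


@dataclass(frozen=True)
class SpirometryMetrics:
    fev1: float  # L
    fvc: float  # L
    pef: float  # L/s
    fev1_fvc_ratio: float
    fet: float  # s
    bev: float  # L
    t0: float  # s, corrected start relative to segment start

    def __post_init__(self) -> None:
        if not 0 < self.fev1 <= self.fvc * (1 + 1e-9):
            raise ValueError("require 0 < fev1 <= fvc")
        if not 0 < self.fev1_fvc_ratio <= 1 + 1e-9:
            raise ValueError("fev1/fvc ratio must be in (0, 1]")
        if self.fet <= 0:
            raise ValueError("fet must be > 0")
        if self.bev < 0:
            raise ValueError("bev must be >= 0")


class ManeuverFlags(NamedTuple):
    bev_ok: bool
    fet_ok: bool
    end_of_test_ok: bool

    @property
    def acceptable(self) -> bool:
        return self.bev_ok and self.fet_ok and self.end_of_test_ok


@dataclass
class AcceptabilityReport:
    maneuver_flags: list[ManeuverFlags]
    session_repeatable_fev1: bool
    session_repeatable_fvc: bool
    n_acceptable: int
    best: SpirometryMetrics


@dataclass
class FlowVolumeLoop:
    """Expiratory limb resampled on a uniform expired-volume grid."""

    volume: np.ndarray  # L, nondecreasing
    flow: np.ndarray  # L/s, >= 0


@dataclass(frozen=True)
class ChannelOffsets:
    pressure_a: float
    pressure_b: float
    gas_no: float
    gas_co: float


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def estimate_zero_offset(trace: RawTrace, rest: Annotation | None = None) -> ChannelOffsets:
    """Per-channel median voltage over the rest window.

    The median over the quiet window is robust to occasional glitches and, for
    symmetric noise, converges to the true zero-pressure offset. If no rest
    annotation is available the first two seconds are used with a warning.
    Note the gas channels' rest level reflects ambient/zero-breath signal, not
    a calibration zero; gas inversion uses the calibrated baseline instead.
    """
    if rest is None:
        rests = trace.segments("rest")
        rest = rests[0] if rests else None
    if rest is None:
        warnings.warn(
            "no rest annotation; estimating channel offsets from the first 2 s",
            stacklevel=2,
        )
        sl = slice(0, max(int(2.0 * trace.sample_rate), 1))
    else:
        if rest.end_s - rest.start_s < 1.0:
            raise MetricError("rest window must be at least 1 s for offset estimation")
        sl = trace.slice_indices(rest)
    return ChannelOffsets(
        pressure_a=float(np.median(trace.v_pressure_a[sl])),
        pressure_b=float(np.median(trace.v_pressure_b[sl])),
        gas_no=float(np.median(trace.v_gas_no[sl])),
        gas_co=float(np.median(trace.v_gas_co[sl])),
    )


def reconstruct_flow(
    trace: RawTrace,
    cal: SensorCalibration,
    offsets: ChannelOffsets | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild the fused exhaled flow series (L/s) from a raw trace.

    Applies rest-window offset correction (the estimated offset replaces the
    nominal zero-pressure voltage), inverts each pressure channel, and fuses
    the two estimates. Inhalation appears as voltage below the offset and is
    clamped to zero flow. Returns ``(flow, flagged)`` where ``flagged`` marks
    out-of-range voltage samples on either channel.
    """
    from dataclasses import replace

    if offsets is None:
        offsets = estimate_zero_offset(trace)
    spec_a = replace(cal.pressure_a, v_offset=offsets.pressure_a)
    spec_b = replace(cal.pressure_b, v_offset=offsets.pressure_b)
    qa, fa = voltage_to_flow(trace.v_pressure_a, spec_a)
    qb, fb = voltage_to_flow(trace.v_pressure_b, spec_b)
    return fuse_dual_sensors(qa, qb, cal), fa | fb


def integrate_volume(flow: np.ndarray, sample_rate: float) -> np.ndarray:
    """Cumulative trapezoidal integral of flow; volume[0] = 0."""
    flow = np.asarray(flow, dtype=float)
    return cumulative_trapezoid(flow, dx=1.0 / sample_rate, initial=0.0)


# ---------------------------------------------------------------------------
# timing and metrics
# ---------------------------------------------------------------------------

def detect_time_zero(
    volume: np.ndarray, flow: np.ndarray, sample_rate: float
) -> tuple[float, float]:
    """Back-extrapolated time zero and back-extrapolated volume.

    The tangent to the volume–time curve at the point of maximal flow is
    extended to the zero-volume axis; its intercept is t0 and the volume
    already expired at t0 is the BEV. Times are relative to the segment start.
    """
    flow = np.asarray(flow, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if flow.size < 2 or float(flow.max()) <= 0.0:
        raise MetricError("no detectable expiratory rise in segment")
    i_pef = int(np.argmax(flow))
    t = np.arange(len(flow)) / sample_rate
    t0 = t[i_pef] - volume[i_pef] / flow[i_pef]
    t0 = float(max(t0, 0.0))
    bev = float(np.interp(t0, t, volume))
    return t0, bev


def end_of_test(
    volume: np.ndarray,
    sample_rate: float,
    plateau_liters: float = EOT_PLATEAU_LITERS,
    window_s: float = EOT_WINDOW_S,
) -> tuple[int, bool]:
    """Earliest index after which every trailing ``window_s`` volume change is
    below ``plateau_liters``.

    Returns ``(index, plateau_found)``; when no plateau is reached before the
    segment end the last index is returned with ``plateau_found=False`` (FVC
    is then read at the segment end and the maneuver's end-of-test flag fails).
    """
    volume = np.asarray(volume, dtype=float)
    n = len(volume)
    if n < 2:
        raise MetricError("segment too short for end-of-test detection")
    w = int(round(window_s * sample_rate))
    if n <= w:
        return n - 1, False
    # volume gained over the next full window; partial trailing windows are
    # no evidence of a plateau
    gain = volume[w:] - volume[: n - w]
    below = gain < plateau_liters
    # plateau must persist: earliest i with below[j] for all j >= i
    persists = np.flip(np.logical_and.accumulate(np.flip(below)))
    if not persists.any():
        return n - 1, False
    return int(np.argmax(persists)), True


def compute_metrics(
    flow: np.ndarray,
    volume: np.ndarray,
    t0: float,
    sample_rate: float,
    bev: float | None = None,
) -> tuple[SpirometryMetrics, bool]:
    """Spirometry metrics for one maneuver segment.

    FEV1 is the volume between t0 and t0 + 1 s with linear interpolation
    between samples; FVC is the maximal cumulative expired volume (the plateau
    volume); PEF the series maximum; FET runs from t0 to the end-of-test.

    Returns ``(metrics, plateau_found)``.
    """
    flow = np.asarray(flow, dtype=float)
    volume = np.asarray(volume, dtype=float)
    t = np.arange(len(flow)) / sample_rate
    if t0 < 0 or t0 > t[-1]:
        raise MetricError("t0 outside the maneuver segment")
    if t[-1] - t0 < 1.0:
        raise MetricError("segment shorter than 1 s after corrected time zero")
    v_t0 = float(np.interp(t0, t, volume))
    fev1 = float(np.interp(t0 + 1.0, t, volume)) - v_t0
    _, plateau = end_of_test(volume, sample_rate)
    fvc = float(volume.max())
    # FET spans the whole recorded expiration; the plateau criterion is
    # reported separately as the end-of-test flag.
    fet = float(t[-1] - t0)
    if bev is None:
        bev = v_t0
    metrics = SpirometryMetrics(
        fev1=fev1,
        fvc=fvc,
        pef=float(flow.max()),
        fev1_fvc_ratio=fev1 / fvc,
        fet=fet,
        bev=float(bev),
        t0=float(t0),
    )
    return metrics, plateau


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

def _flags_for(metrics: SpirometryMetrics, plateau_found: bool) -> ManeuverFlags:
    bev_ok = metrics.bev < max(REPEATABILITY_LITERS, 0.05 * metrics.fvc)
    fet_ok = metrics.fet >= 6.0
    return ManeuverFlags(bev_ok=bev_ok, fet_ok=fet_ok, end_of_test_ok=plateau_found)


def grade_session(
    metrics_list: Sequence[SpirometryMetrics],
    flags_list: Sequence[ManeuverFlags] | None = None,
) -> AcceptabilityReport:
    """Grade a session of maneuvers.

    Repeatability holds for FEV1 (resp. FVC) iff the two largest values across
    maneuvers differ by at most 0.150 L (ties trivially pass). The "best"
    metrics take the maximum FEV1 and maximum FVC independently, possibly from
    different maneuvers; ratio, timing and BEV are reported from the maneuver
    with the largest FEV1 + FVC sum, the standard best-test convention.
    """
    if len(metrics_list) < 2:
        raise GradingUnavailableError(
            f"grading requires >= 2 maneuvers, got {len(metrics_list)}"
        )
    if flags_list is None:
        flags_list = [ManeuverFlags(True, True, True)] * len(metrics_list)

    fev1s = sorted((m.fev1 for m in metrics_list), reverse=True)
    fvcs = sorted((m.fvc for m in metrics_list), reverse=True)
    rep_fev1 = (fev1s[0] - fev1s[1]) <= REPEATABILITY_LITERS
    rep_fvc = (fvcs[0] - fvcs[1]) <= REPEATABILITY_LITERS

    best_test = max(metrics_list, key=lambda m: m.fev1 + m.fvc)
    best = SpirometryMetrics(
        fev1=fev1s[0],
        fvc=fvcs[0],
        pef=max(m.pef for m in metrics_list),
        fev1_fvc_ratio=best_test.fev1_fvc_ratio,
        fet=best_test.fet,
        bev=best_test.bev,
        t0=best_test.t0,
    )
    return AcceptabilityReport(
        maneuver_flags=list(flags_list),
        session_repeatable_fev1=rep_fev1,
        session_repeatable_fvc=rep_fvc,
        n_acceptable=sum(f.acceptable for f in flags_list),
        best=best,
    )


# ---------------------------------------------------------------------------
# session driver
# ---------------------------------------------------------------------------

def flow_volume_loop(flow: np.ndarray, volume: np.ndarray, n_points: int = 200) -> FlowVolumeLoop:
    """Resample the expiratory limb onto a uniform expired-volume grid."""
    flow = np.maximum(np.asarray(flow, dtype=float), 0.0)
    vol = np.maximum.accumulate(np.asarray(volume, dtype=float))
    grid = np.linspace(0.0, vol[-1], n_points)
    return FlowVolumeLoop(volume=grid, flow=np.interp(grid, vol, flow))


@dataclass
class ManeuverResult:
    metrics: SpirometryMetrics
    flags: ManeuverFlags
    loop: FlowVolumeLoop
    flagged_sample_fraction: float
    usable: bool = True


@dataclass
class SessionAnalysis:
    maneuvers: list[ManeuverResult]
    report: AcceptabilityReport | None
    flow: np.ndarray
    volume_by_maneuver: list[np.ndarray]
    offsets: ChannelOffsets


def analyze_maneuver(
    flow_segment: np.ndarray,
    sample_rate: float,
    flagged: np.ndarray | None = None,
) -> ManeuverResult:
    """Full metric pipeline for one already-reconstructed maneuver segment."""
    volume = integrate_volume(flow_segment, sample_rate)
    t0, bev = detect_time_zero(volume, flow_segment, sample_rate)
    metrics, plateau = compute_metrics(flow_segment, volume, t0, sample_rate, bev=bev)
    frac = float(np.mean(flagged)) if flagged is not None else 0.0
    return ManeuverResult(
        metrics=metrics,
        flags=_flags_for(metrics, plateau),
        loop=flow_volume_loop(flow_segment, volume),
        flagged_sample_fraction=frac,
    )


def analyze_session(trace: RawTrace, cal: SensorCalibration) -> SessionAnalysis:
    """Reconstruct flow for a whole session and analyse each annotated maneuver."""
    offsets = estimate_zero_offset(trace)
    flow, flagged = reconstruct_flow(trace, cal, offsets)
    maneuvers: list[ManeuverResult] = []
    volumes: list[np.ndarray] = []
    for ann in trace.segments("maneuver"):
        sl = trace.slice_indices(ann)
        res = analyze_maneuver(flow[sl], trace.sample_rate, flagged[sl])
        maneuvers.append(res)
        volumes.append(integrate_volume(flow[sl], trace.sample_rate))
    report = None
    if len(maneuvers) >= 2:
        report = grade_session([m.metrics for m in maneuvers], [m.flags for m in maneuvers])
    return SessionAnalysis(
        maneuvers=maneuvers,
        report=report,
        flow=flow,
        volume_by_maneuver=volumes,
        offsets=offsets,
    )


# ---------------------------------------------------------------------------
# percent predicted (pluggable)
# ---------------------------------------------------------------------------

class ReferenceEquationRegistry:
    """Pluggable registry of reference ("predicted") equations.

    Register a callable per metric; it receives a demographics mapping (age,
    sex, height_cm, ...) and returns the predicted value in the metric's
    units, or raises KeyError for strata it does not cover. No equations ship
    by default — reference-equation choice is a clinical decision left to the
    caller.
    """

    def __init__(self) -> None:
        self._eqs: dict[str, Callable[[dict], float]] = {}

    def register(self, metric: str, fn: Callable[[dict], float]) -> None:
        self._eqs[metric.lower()] = fn

    def predict(self, metric: str, demographics: dict) -> float:
        try:
            fn = self._eqs[metric.lower()]
        except KeyError:
            raise UnsupportedDemographicsError(
                f"no reference equation registered for metric {metric!r}"
            ) from None
        try:
            return float(fn(demographics))
        except KeyError as exc:
            raise UnsupportedDemographicsError(
                f"reference equation for {metric!r} does not cover stratum {exc}"
            ) from None


def percent_predicted(
    measured: float,
    metric: str,
    demographics: dict,
    registry: ReferenceEquationRegistry,
) -> float:
    """100 · measured / predicted for the given demographic stratum."""
    predicted = registry.predict(metric, demographics)
    if predicted <= 0:
        raise ValueError("predicted value must be positive")
    return 100.0 * measured / predicted
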