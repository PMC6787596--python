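"""Sensor transduction models for a dual-range pneumotachograph with breath-gas
sensing.

The virtual device mirrors a mobile spirometer built around a fixed airflow
obstruction instrumented with two differential pressure sensors — a high-range
sensor ("A", 50–900 L/min) and a low-range sensor ("B", 15–100 L/min) — plus two
electrochemical gas sensors (NO, CO) read out through a potentiostat and
transimpedance amplifier, lumped here into a single linear volts-per-ppm gain.

Forward direction (physiology → electronics)::

    flow Q  --ΔP = k·Q²·sign(Q)-->  pressure  --V = V0 + s·ΔP, ADC-->  volts
    conc C  --V = Vb + S·C, ADC-->  volts

Inverse direction (electronics → physiology) is exposed per sensor together
with a dual-range fusion rule that cross-fades between the two pressure
sensors inside their overlap band.

Units: flow in L/s (ranges quoted in L/min as printed on the sensors),
pressure in kPa, voltage in V, gas concentration in ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Union

import numpy as np

__all__ = [
    "PressureSensorSpec",
    "GasSensorSpec",
    "SensorCalibration",
    "default_calibration",
    "flow_to_pressure",
    "pressure_to_voltage",
    "voltage_to_flow",
    "fuse_dual_sensors",
    "gas_voltage_to_concentration",
    "LPM_PER_LPS",
]

#: L/min per L/s
LPM_PER_LPS = 60.0

RngLike = Union[int, np.random.Generator, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class PressureSensorSpec:
    """One differential pressure sensor behind the fixed orifice.

    Parameters
    ----------
    name : str
        "A" (high range) or "B" (low range).
    flow_min_lpm, flow_max_lpm : float
        Usable flow range in L/min.
    orifice_coeff_k : float
        Orifice coefficient k in kPa/(L/s)^2; ΔP = k·Q².
    v_offset : float
        Output voltage at zero differential pressure.
    v_span : float
        Sensitivity in V/kPa.
    noise_sd : float
        Additive voltage noise SD (V).
    adc_bits : int
        ADC resolution; quantisation step is v_ref/(2**adc_bits - 1).
    v_ref : float
        ADC reference / supply voltage (V); output clipped to [0, v_ref].
    """

    name: str
    flow_min_lpm: float
    flow_max_lpm: float
    orifice_coeff_k: float
    v_offset: float
    v_span: float
    noise_sd: float = 0.001
    adc_bits: int = 10
    v_ref: float = 5.0

    def __post_init__(self) -> None:
        if not self.flow_min_lpm < self.flow_max_lpm:
            raise ValueError("flow_min_lpm must be < flow_max_lpm")
        if self.orifice_coeff_k <= 0:
            raise ValueError("orifice_coeff_k must be > 0")
        if self.v_span <= 0:
            raise ValueError("v_span must be > 0")
        if self.adc_bits < 8:
            raise ValueError("adc_bits must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def adc_step(self) -> float:
        return self.v_ref / (2**self.adc_bits - 1)

    @property
    def full_scale_pressure(self) -> float:
        """ΔP at flow_max (kPa)."""
        return self.orifice_coeff_k * (self.flow_max_lpm / LPM_PER_LPS) ** 2


@dataclass(frozen=True)
class GasSensorSpec:
    """Electrochemical gas sensor with lumped linear readout.

    ``sensitivity`` folds the cell's current-per-ppm and the transimpedance
    gain into one V/ppm constant; ``v_baseline`` is the output at zero
    analyte. ``detection_floor`` is the lowest concentration the channel is
    calibrated to resolve (readings below it are flagged, not discarded).
    """

    analyte: str  # "NO" | "CO"
    sensitivity: float  # V/ppm
    v_baseline: float
    detection_floor: float  # ppm
    range_max: float  # ppm
    noise_sd: float = 0.003
    v_ref: float = 5.0

    def __post_init__(self) -> None:
        if self.analyte not in ("NO", "CO"):
            raise ValueError("analyte must be 'NO' or 'CO'")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        if self.range_max <= self.detection_floor:
            raise ValueError("range_max must exceed detection_floor")


@dataclass(frozen=True)
class SensorCalibration:
    """Full device calibration: both pressure sensors, both gas channels,
    sampling rate and the fusion cross-fade band (L/min)."""

    pressure_a: PressureSensorSpec
    pressure_b: PressureSensorSpec
    gas_no: GasSensorSpec
    gas_co: GasSensorSpec
    sample_rate: float = 100.0
    fusion_low_edge_lpm: float = 50.0
    fusion_high_edge_lpm: float = 100.0

    def __post_init__(self) -> None:
        if self.sample_rate < 50.0:
            raise ValueError("sample_rate must be >= 50 Hz")
        lo, hi = self.fusion_low_edge_lpm, self.fusion_high_edge_lpm
        if not lo < hi:
            raise ValueError("fusion band must have low < high edge")
        overlap_lo = max(self.pressure_a.flow_min_lpm, self.pressure_b.flow_min_lpm)
        overlap_hi = min(self.pressure_a.flow_max_lpm, self.pressure_b.flow_max_lpm)
        if lo < overlap_lo or hi > overlap_hi:
            raise ValueError(
                f"fusion band [{lo}, {hi}] L/min outside sensor overlap "
                f"[{overlap_lo}, {overlap_hi}] L/min"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SensorCalibration":
        d = dict(d)
        for key, typ in (
            ("pressure_a", PressureSensorSpec),
            ("pressure_b", PressureSensorSpec),
            ("gas_no", GasSensorSpec),
            ("gas_co", GasSensorSpec),
        ):
            if isinstance(d.get(key), dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def perturbed(self, rel_sd: float, rng: RngLike = None) -> "SensorCalibration":
        """Return a copy with pressure spans/offsets jittered by a relative
        Gaussian factor — models unit-to-unit calibration error between two
        physical devices built to the same nominal design."""
        rng = _as_rng(rng)

        def jig(spec: PressureSensorSpec) -> PressureSensorSpec:
            return replace(
                spec,
                v_span=spec.v_span * (1.0 + rel_sd * rng.standard_normal()),
                v_offset=spec.v_offset * (1.0 + rel_sd * rng.standard_normal()),
            )

        return replace(self, pressure_a=jig(self.pressure_a), pressure_b=jig(self.pressure_b))


def default_calibration() -> SensorCalibration:
    """Documented default device profile.

    Sensor A emulates a 0–10 kPa piezoresistive part spanning 50–900 L/min;
    sensor B a ±0.5 kPa low-range part spanning 15–100 L/min. k is chosen per
    sensor so full-scale pressure corresponds to flow_max. The ADC is 10-bit
    over 0–5 V. Gas gains place the physiologic NO and CO ranges comfortably
    inside the voltage span with floors at 0.03 ppm NO and 2 ppm CO.
    """
    q_max_a = 900.0 / LPM_PER_LPS  # 15 L/s
    q_max_b = 100.0 / LPM_PER_LPS
    p_fs_a, p_fs_b = 10.0, 0.5  # kPa
    pa = PressureSensorSpec(
        name="A",
        flow_min_lpm=50.0,
        flow_max_lpm=900.0,
        orifice_coeff_k=p_fs_a / q_max_a**2,
        v_offset=0.2,
        v_span=4.5 / p_fs_a,
    )
    pb = PressureSensorSpec(
        name="B",
        flow_min_lpm=15.0,
        flow_max_lpm=100.0,
        orifice_coeff_k=p_fs_b / q_max_b**2,
        v_offset=0.2,
        v_span=4.5 / p_fs_b,
    )
    no = GasSensorSpec(analyte="NO", sensitivity=2.0, v_baseline=0.6,
                       detection_floor=0.03, range_max=2.0)
    co = GasSensorSpec(analyte="CO", sensitivity=0.4, v_baseline=0.6,
                       detection_floor=2.0, range_max=10.0)
    return SensorCalibration(pressure_a=pa, pressure_b=pb, gas_no=no, gas_co=co)


# ---------------------------------------------------------------------------
# forward transduction
# ---------------------------------------------------------------------------

def flow_to_pressure(flow_lps, spec: PressureSensorSpec):
    """Signed quadratic orifice law: ΔP = k·Q²·sign(Q)  (kPa)."""
    q = np.asarray(flow_lps, dtype=float)
    return spec.orifice_coeff_k * q * np.abs(q)


def quantize_voltage(v, spec: PressureSensorSpec | GasSensorSpec):
    """Round to the nearest ADC level on [0, v_ref]."""
    step = spec.v_ref / (2 ** getattr(spec, "adc_bits", 10) - 1)
    return np.round(np.asarray(v, dtype=float) / step) * step


def pressure_to_voltage(
    pressure_kpa,
    spec: PressureSensorSpec,
    noisy: bool = False,
    rng: RngLike = None,
    quantize: bool = True,
):
    """Piezoresistive bridge + ADC: V = clip(V0 + s·ΔP + ε, 0, v_ref), quantised.

    Deterministic for a given ``rng`` seed; ``quantize=False`` bypasses the ADC
    (useful for analytic identities).
    """
    p = np.asarray(pressure_kpa, dtype=float)
    v = spec.v_offset + spec.v_span * p
    if noisy and spec.noise_sd > 0:
        v = v + _as_rng(rng).normal(0.0, spec.noise_sd, size=p.shape)
    v = np.clip(v, 0.0, spec.v_ref)
    if quantize:
        v = quantize_voltage(v, spec)
    return v


def gas_concentration_to_voltage(
    conc_ppm,
    spec: GasSensorSpec,
    noisy: bool = False,
    rng: RngLike = None,
    quantize: bool = True,
):
    """Linear electrochemical readout: V = clip(Vb + S·C + ε, 0, v_ref)."""
    c = np.asarray(conc_ppm, dtype=float)
    v = spec.v_baseline + spec.sensitivity * c
    if noisy and spec.noise_sd > 0:
        v = v + _as_rng(rng).normal(0.0, spec.noise_sd, size=c.shape)
    v = np.clip(v, 0.0, spec.v_ref)
    if quantize:
        v = quantize_voltage(v, spec)
    return v


# ---------------------------------------------------------------------------
# inverse transduction
# ---------------------------------------------------------------------------

def voltage_to_flow(volts, spec: PressureSensorSpec):
    """Invert one pressure channel to exhaled flow (L/s).

    Q = sqrt(max((V − V0)/s, 0)/k). Voltages below the zero-pressure offset map
    to zero flow (inhalation and noise excursions are clamped: only forced
    exhalation is analysed). Samples outside [0, v_ref] are flagged rather than
    raised, so a streaming glitch does not abort an analysis.

    Returns
    -------
    flow : ndarray (L/s)
    flagged : boolean ndarray, True where the input voltage was out of range.
    """
    v = np.asarray(volts, dtype=float)
    flagged = (v < 0.0) | (v > spec.v_ref)
    p = np.maximum((np.clip(v, 0.0, spec.v_ref) - spec.v_offset) / spec.v_span, 0.0)
    q = np.sqrt(p / spec.orifice_coeff_k)
    return q, flagged


def fuse_dual_sensors(flow_a, flow_b, cal: SensorCalibration, q_ref=None):
    """Blend the two single-sensor flow estimates into one series.

    Below the fusion band the low-range sensor B estimate is used, above it the
    high-range sensor A estimate; inside the band a linear cross-fade
    w = (Q_ref − low)/(high − low) gives (1−w)·B + w·A. The reference flow
    Q_ref defaults to sensor A's own estimate so the weight does not depend on
    the output being formed; pass ``q_ref`` to override.
    """
    qa = np.asarray(flow_a, dtype=float)
    qb = np.asarray(flow_b, dtype=float)
    if qa.shape != qb.shape:
        raise ValueError(f"mismatched series lengths: {qa.shape} vs {qb.shape}")
    qr = qa if q_ref is None else np.asarray(q_ref, dtype=float)
    lo = cal.fusion_low_edge_lpm / LPM_PER_LPS
    hi = cal.fusion_high_edge_lpm / LPM_PER_LPS
    w = np.clip((qr - lo) / (hi - lo), 0.0, 1.0)
    return (1.0 - w) * qb + w * qa


def gas_voltage_to_concentration(volts, spec: GasSensorSpec):
    """Invert a gas channel: C = (V − Vb)/S, clamped at zero.

    Samples below the calibrated detection floor are flagged below-floor but
    retained, so a downstream summary can report the below-floor fraction.

    Returns
    -------
    conc : ndarray (ppm)
    below_floor : boolean ndarray
    """
    v = np.asarray(volts, dtype=float)
    c = np.maximum((v - spec.v_baseline) / spec.sensitivity, 0.0)
    return c, c < spec.detection_floor
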