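"""Synthetic breath-session generator.

Produces physiologically structured sessions — 60 s of tidal breathing (during
which exhaled NO and CO are sampled), 5 s of rest, then forced expiratory
maneuvers of at least six seconds — and passes them through the device forward
model to yield multi-channel voltage traces with exact ground truth attached.

The forced expiratory flow profile is a linear rise to peak flow followed by a
generalised-exponential decay

    Q(t_r + t') = PEF · exp(−(t'/τ)^b),

whose two free constants (τ, b) are solved numerically so the maneuver delivers
the requested FEV1 and FVC. The partial integrals have a closed form through
the lower incomplete gamma function, so the solve and the reported ground truth
are exact rather than grid-based. Disease phenotypes differ in their anchor
volumes and in the decay concavity: b < 1 produces the scooped ("obstructive")
expiratory limb characteristic of COPD, b ≳ 1 the convex healthy limb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gamma as gamma_fn, gammainc

from .device_model import (
    RngLike,
    SensorCalibration,
    _as_rng,
    default_calibration,
    flow_to_pressure,
    gas_concentration_to_voltage,
    pressure_to_voltage,
)
from .errors import ParameterInfeasibleError

__all__ = [
    "ManeuverParams",
    "ManeuverTruth",
    "SessionScript",
    "Annotation",
    "RawTrace",
    "GroundTruth",
    "CohortSubject",
    "PHENOTYPE_PRESETS",
    "GROUP_ANCHORS",
    "make_expiratory_flow",
    "make_session",
    "make_cohort",
    "draw_subject_truth",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManeuverParams:
    """Target quantities for one forced expiratory maneuver.

    ``decay_shape`` is the concavity parameter b of the generalised-exponential
    decay (>= 1 exponential-like, < 1 scooped/obstructive); it serves as the
    solver's initial guess, the solved value lands nearby when the volume
    targets permit.
    """

    fev1_true: float  # L
    fvc_true: float  # L
    pef_true: float  # L/s
    rise_time: float = 0.1  # s
    decay_shape: float = 1.0
    fet_total: float = 6.0  # s
    phenotype: str = "healthy"

    def __post_init__(self) -> None:
        if not 0 < self.fev1_true <= self.fvc_true:
            raise ValueError("require 0 < fev1_true <= fvc_true")
        if self.pef_true < self.fvc_true / self.fet_total:
            raise ValueError("pef_true must be >= fvc_true / fet_total")
        if self.fet_total < 6.0:
            raise ValueError("fet_total must be >= 6 s")
        if not 0 < self.rise_time <= 0.5:
            raise ValueError("rise_time must be in (0, 0.5] s")
        if self.decay_shape <= 0:
            raise ValueError("decay_shape must be > 0")


class ManeuverTruth(NamedTuple):
    """Exact achieved metrics of a generated maneuver (closed form).

    ``fev1`` is timed from the back-extrapolated time zero t0 = rise_time/2,
    the same convention the analysis pipeline uses.
    """

    fev1: float
    fvc: float
    pef: float
    fet: float
    t0: float
    bev: float
    tau: float
    shape_b: float


@dataclass(frozen=True)
class SessionScript:
    """Protocol timing and true analyte levels for one recording session."""

    tidal_duration: float = 60.0  # s
    rest_duration: float = 5.0  # s
    n_maneuvers: int = 3
    gas_no_true_ppb: float = 50.0
    gas_co_true_ppm: float = 3.04
    gps: tuple[float, float] | None = (38.5449, -121.7405)
    subject_group: str = "control"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maneuvers < 1:
            raise ValueError("n_maneuvers must be >= 1")
        if self.gas_no_true_ppb < 0 or self.gas_co_true_ppm < 0:
            raise ValueError("gas concentrations must be >= 0")
        if self.tidal_duration < 0 or self.rest_duration < 0:
            raise ValueError("durations must be >= 0")


class Annotation(NamedTuple):
    label: str
    start_s: float
    end_s: float


@dataclass
class RawTrace:
    """Uniformly sampled multi-channel voltage record from the (virtual) device."""

    sample_rate: float
    t: np.ndarray
    v_pressure_a: np.ndarray
    v_pressure_b: np.ndarray
    v_gas_no: np.ndarray
    v_gas_co: np.ndarray
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("v_pressure_a", "v_pressure_b", "v_gas_no", "v_gas_co"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length differs from time axis")

    def segments(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]

    def slice_indices(self, ann: Annotation) -> slice:
        i0 = int(np.searchsorted(self.t, ann.start_s - 1e-9))
        i1 = int(np.searchsorted(self.t, ann.end_s - 1e-9))
        return slice(i0, i1)


@dataclass
class GroundTruth:
    """Simulator-side truth attached to a generated session."""

    maneuvers: list[ManeuverTruth]
    gas_no_ppb: float
    gas_co_ppm: float
    subject_group: str


# Anchor values per subject group: (FEV1 mean, FEV1 SD, FVC mean, FVC SD) in L,
# typical PEF (L/s) and decay concavity. Volume anchors follow the study
# cohort's baseline spirometry; PEF/shape are generator choices giving
# phenotype-typical loop shapes.
GROUP_ANCHORS: dict[str, dict[str, float]] = {
    "control": dict(fev1_mean=3.74, fev1_sd=0.54, fvc_mean=4.42, fvc_sd=0.66,
                    pef=8.5, shape=1.3, fet=7.0),
    "asthma": dict(fev1_mean=2.37, fev1_sd=1.10, fvc_mean=3.02, fvc_sd=1.24,
                   pef=6.0, shape=0.9, fet=7.5),
    "COPD": dict(fev1_mean=1.06, fev1_sd=0.55, fvc_mean=2.05, fvc_sd=0.70,
                 pef=3.5, shape=0.6, fet=9.0),
}

#: Ready-made maneuver parameter sets at the group mean values. Expirations
#: run comfortably past the six-second minimum so graded maneuvers can meet
#: the FET rule after time-zero correction.
PHENOTYPE_PRESETS: dict[str, ManeuverParams] = {
    "healthy": ManeuverParams(3.74, 4.42, 8.5, decay_shape=1.3, fet_total=7.0,
                              phenotype="healthy"),
    "asthma": ManeuverParams(2.37, 3.02, 6.0, decay_shape=0.9, fet_total=7.5,
                             phenotype="asthma"),
    "COPD": ManeuverParams(1.06, 2.05, 3.5, decay_shape=0.6, fet_total=9.0,
                           phenotype="COPD"),
}

_GROUP_TO_PHENOTYPE = {"control": "healthy", "asthma": "asthma", "COPD": "COPD"}


# ---------------------------------------------------------------------------
# single maneuver
# ---------------------------------------------------------------------------

def _decay_volume(t_after_rise: float, pef: float, tau: float, b: float) -> float:
    """∫_0^t PEF·exp(−(u/τ)^b) du via the regularised lower incomplete gamma."""
    if t_after_rise <= 0:
        return 0.0
    x = (t_after_rise / tau) ** b
    return pef * (tau / b) * gamma_fn(1.0 / b) * gammainc(1.0 / b, x)


def _profile_volume(t: float, p: ManeuverParams, tau: float, b: float) -> float:
    """Cumulative expired volume of the continuous profile at time t."""
    tr = p.rise_time
    if t <= tr:
        return p.pef_true * t * t / (2.0 * tr)
    return p.pef_true * tr / 2.0 + _decay_volume(t - tr, p.pef_true, tau, b)


def solve_decay_constants(params: ManeuverParams) -> tuple[float, float]:
    """Solve (τ, b) so the profile delivers fev1_true and fvc_true.

    Raises
    ------
    ParameterInfeasibleError
        If the requested combination cannot be met by the smooth profile
        within 0.5% on both targets; the message names the violated constraint.
    """
    p = params
    t0 = p.rise_time / 2.0
    v_rise = p.pef_true * p.rise_time / 2.0
    v_t0 = p.pef_true * p.rise_time / 8.0

    if v_rise >= p.fev1_true:
        raise ParameterInfeasibleError(
            f"rise volume {v_rise:.3f} L already exceeds fev1_true "
            f"{p.fev1_true:.3f} L: pef_true·rise_time/2 must be < fev1_true"
        )
    if p.fev1_true > 0.99 * p.pef_true * 1.0:
        raise ParameterInfeasibleError(
            f"pef_true {p.pef_true:.2f} L/s too low to deliver fev1_true "
            f"{p.fev1_true:.2f} L within the first second"
        )
    if (p.fvc_true - p.fev1_true) < 0.005 * p.fvc_true and p.fet_total > t0 + 1.25:
        raise ParameterInfeasibleError(
            "fev1_true ≈ fvc_true leaves no volume for the post-1-s tail: a "
            "smooth decay sustained to fet_total must expire volume after 1 s"
        )

    def resid(x: np.ndarray) -> list[float]:
        tau, b = np.exp(x)
        g1 = (_profile_volume(t0 + 1.0, p, tau, b) - v_t0) - p.fev1_true
        g2 = _profile_volume(p.fet_total, p, tau, b) - p.fvc_true
        return [g1 / p.fev1_true, g2 / p.fvc_true]

    tau0 = float(np.clip((p.fvc_true - v_rise) / p.pef_true, 0.05, 10.0))
    x0 = np.log([tau0, p.decay_shape])
    sol = least_squares(
        resid, x0,
        bounds=(np.log([0.01, 0.15]), np.log([40.0, 5.0])),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    tau, b = np.exp(sol.x)
    g1, g2 = resid(sol.x)
    if abs(g1) > 0.005 or abs(g2) > 0.005:
        raise ParameterInfeasibleError(
            f"no (τ, b) meets fev1_true={p.fev1_true:.3f} L and "
            f"fvc_true={p.fvc_true:.3f} L at pef_true={p.pef_true:.2f} L/s "
            f"(relative residuals {g1:.3%}, {g2:.3%})"
        )
    return float(tau), float(b)


def make_expiratory_flow(
    params: ManeuverParams, sample_rate: float = 100.0
) -> tuple[np.ndarray, np.ndarray, ManeuverTruth]:
    """Generate one forced expiratory flow series plus its exact ground truth.

    Returns
    -------
    t : ndarray of sample times (s, from maneuver start)
    flow : ndarray (L/s)
    truth : ManeuverTruth with closed-form achieved metrics.
    """
    tau, b = solve_decay_constants(params)
    p = params
    t = np.arange(0.0, p.fet_total + 0.5 / sample_rate, 1.0 / sample_rate)
    flow = np.where(
        t <= p.rise_time,
        p.pef_true * t / p.rise_time,
        p.pef_true * np.exp(-(np.maximum(t - p.rise_time, 0.0) / tau) ** b),
    )
    t0 = p.rise_time / 2.0
    v_t0 = p.pef_true * p.rise_time / 8.0
    truth = ManeuverTruth(
        fev1=_profile_volume(t0 + 1.0, p, tau, b) - v_t0,
        fvc=_profile_volume(p.fet_total, p, tau, b),
        pef=float(flow.max()),
        fet=p.fet_total - t0,
        t0=t0,
        bev=v_t0,
        tau=tau,
        shape_b=b,
    )
    return t, flow, truth


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------

_TIDAL_FREQ = 0.25  # Hz
_TIDAL_VOLUME = 0.5  # L
_INHALE_DURATION = 1.5  # s
_RECOVERY_DURATION = 8.0  # s
_GAS_EQUILIBRATION_TAU = 1.5  # s
_GAS_DRIFT_SD_PER_MIN = 0.005  # relative drift-rate SD, per minute


def _params_for_script(script: SessionScript) -> ManeuverParams:
    phen = _GROUP_TO_PHENOTYPE.get(script.subject_group)
    if phen is None:
        raise ValueError(f"unknown subject_group {script.subject_group!r}")
    return PHENOTYPE_PRESETS[phen]


def make_session(
    script: SessionScript,
    params: ManeuverParams | None = None,
    cal: SensorCalibration | None = None,
    *,
    noisy: bool = True,
    quantize: bool = True,
    maneuver_cv: float = 0.0,
) -> tuple[RawTrace, GroundTruth]:
    """Simulate one full protocol session through the device forward model.

    Timeline: tidal breathing (gas sampled here), rest, then ``n_maneuvers``
    forced expirations each preceded by a deep inhalation and separated by
    recovery breathing. Deterministic for a fixed ``script.rng_seed``.

    ``maneuver_cv`` applies a multiplicative lognormal maneuver-to-maneuver
    effort factor (same factor to FEV1/FVC/PEF, i.e. the whole flow profile),
    modelling within-subject variability.
    """
    cal = cal or default_calibration()
    if params is None:
        params = _params_for_script(script)
    rng = _as_rng(script.rng_seed)
    fs = cal.sample_rate
    dt = 1.0 / fs

    # Base maneuver solved once; per-maneuver effort scales the whole profile.
    t_man, base_flow, base_truth = make_expiratory_flow(params, fs)

    chunks: list[np.ndarray] = []
    annotations: list[Annotation] = []
    cursor = 0.0

    def add(label: str, flow_chunk: np.ndarray) -> None:
        nonlocal cursor
        chunks.append(flow_chunk)
        dur = len(flow_chunk) * dt
        annotations.append(Annotation(label, cursor, cursor + dur))
        cursor += dur

    # 1) tidal breathing: sinusoidal flow sized for ~0.5 L tidal volume
    n_tidal = int(round(script.tidal_duration * fs))
    tt = np.arange(n_tidal) * dt
    amp = _TIDAL_VOLUME * np.pi * _TIDAL_FREQ  # peak flow of the sinusoid
    add("tidal", amp * np.sin(2 * np.pi * _TIDAL_FREQ * tt))

    # 2) rest
    add("rest", np.zeros(int(round(script.rest_duration * fs))))

    # 3) maneuvers with deep inhalation before and recovery breathing between
    truths: list[ManeuverTruth] = []
    n_inh = int(round(_INHALE_DURATION * fs))
    ti = np.arange(n_inh) * dt
    inhale_amp = params.fvc_true * np.pi / (2.0 * _INHALE_DURATION)
    inhale = -inhale_amp * np.sin(np.pi * ti / _INHALE_DURATION)
    n_rec = int(round(_RECOVERY_DURATION * fs))
    trc = np.arange(n_rec) * dt
    recovery = amp * np.sin(2 * np.pi * _TIDAL_FREQ * trc)

    for j in range(script.n_maneuvers):
        effort = math.exp(rng.normal(0.0, maneuver_cv)) if maneuver_cv > 0 else 1.0
        add("inhale", inhale * effort)
        add("maneuver", base_flow * effort)
        truths.append(
            base_truth._replace(
                fev1=base_truth.fev1 * effort,
                fvc=base_truth.fvc * effort,
                pef=base_truth.pef * effort,
            )
        )
        if j < script.n_maneuvers - 1:
            add("recovery", recovery)

    flow = np.concatenate(chunks)
    n = len(flow)
    t = np.arange(n) * dt

    # gas concentration profile: equilibration transient + random linear drift
    co_true = script.gas_co_true_ppm
    no_true = script.gas_no_true_ppb / 1000.0  # ppm
    equil = 1.0 - np.exp(-t / _GAS_EQUILIBRATION_TAU)
    drift_rate_co = rng.normal(0.0, _GAS_DRIFT_SD_PER_MIN) / 60.0 if noisy else 0.0
    drift_rate_no = rng.normal(0.0, _GAS_DRIFT_SD_PER_MIN) / 60.0 if noisy else 0.0
    conc_co = co_true * equil * (1.0 + drift_rate_co * t)
    conc_no = no_true * equil * (1.0 + drift_rate_no * t)

    va = pressure_to_voltage(flow_to_pressure(flow, cal.pressure_a), cal.pressure_a,
                             noisy=noisy, rng=rng, quantize=quantize)
    vb = pressure_to_voltage(flow_to_pressure(flow, cal.pressure_b), cal.pressure_b,
                             noisy=noisy, rng=rng, quantize=quantize)
    vno = gas_concentration_to_voltage(conc_no, cal.gas_no, noisy=noisy, rng=rng,
                                       quantize=quantize)
    vco = gas_concentration_to_voltage(conc_co, cal.gas_co, noisy=noisy, rng=rng,
                                       quantize=quantize)

    trace = RawTrace(
        sample_rate=fs, t=t, v_pressure_a=va, v_pressure_b=vb,
        v_gas_no=vno, v_gas_co=vco, annotations=annotations,
    )
    truth = GroundTruth(
        maneuvers=truths,
        gas_no_ppb=script.gas_no_true_ppb,
        gas_co_ppm=script.gas_co_true_ppm,
        subject_group=script.subject_group,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# paired-device cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSubject:
    """One simulated subject with true lung function and (optionally) a
    session recorded on each of two virtual devices."""

    subject_id: str
    group: str
    params: ManeuverParams
    session_a: tuple[RawTrace, GroundTruth] | None = None
    session_b: tuple[RawTrace, GroundTruth] | None = None


def _lognormal_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def draw_subject_truth(group: str, rng: RngLike = None) -> ManeuverParams:
    """Draw one subject's true maneuver parameters from the group anchors.

    FEV1 and FVC are correlated lognormals whose arithmetic means/SDs match
    the group anchor table exactly (lognormality keeps volumes positive
    without truncation bias). PEF scales with the subject's FEV1 deviation
    from the group mean; light clipping enforces profile feasibility.
    """
    rng = _as_rng(rng)
    a = GROUP_ANCHORS[group]
    mu1, s1 = _lognormal_moments(a["fev1_mean"], a["fev1_sd"])
    mu2, s2 = _lognormal_moments(a["fvc_mean"], a["fvc_sd"])
    rho = 0.9
    z1 = rng.standard_normal()
    z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal()
    fev1 = math.exp(mu1 + s1 * z1)
    fvc = math.exp(mu2 + s2 * z2)
    fev1 = min(fev1, 0.97 * fvc)
    fet = a["fet"]
    pef = a["pef"] * (fev1 / a["fev1_mean"]) ** 0.8 * math.exp(rng.normal(0.0, 0.10))
    pef = max(pef, 1.35 * fev1, 1.1 * fvc / fet, 0.5)
    # guarantee the profile solve is feasible: a severely obstructed draw
    # (very low FEV1/FVC with a long tail) may need a lower peak flow than the
    # anchor scaling suggests, so retry with PEF eased toward its floor
    pef_floor = max(1.2 * fev1, 1.1 * fvc / fet, 0.3)
    for scale in (1.0, 0.85, 0.7, 0.55, 0.45, None):
        trial_pef = pef_floor if scale is None else max(pef * scale, pef_floor)
        params = ManeuverParams(
            fev1_true=fev1, fvc_true=fvc, pef_true=trial_pef,
            decay_shape=a["shape"], fet_total=fet,
            phenotype=_GROUP_TO_PHENOTYPE[group],
        )
        try:
            _, b = solve_decay_constants(params)
        except ParameterInfeasibleError:
            continue
        # a needle peak that collapses quasi-instantly (tiny b) is not a
        # physiologic effort; prefer a lower PEF with a smooth decay
        if b >= 0.25 or scale is None:
            return params
    raise ParameterInfeasibleError(
        f"could not realise drawn subject (fev1={fev1:.2f}, fvc={fvc:.2f})"
    )


def make_cohort(
    n_subjects: int,
    group_mix: dict[str, float] | str | None = None,
    seed: int = 0,
    *,
    cal: SensorCalibration | None = None,
    maneuver_cv: float = 0.02,
    calibration_jitter: float = 0.002,
    generate_traces: bool = True,
    n_maneuvers: int = 3,
) -> list[CohortSubject]:
    """Simulate a benchmark cohort: each subject performs ``n_maneuvers``
    forced maneuvers on each of two virtual devices.

    The two devices share the nominal calibration but carry independent
    unit-to-unit calibration jitter and independent noise; maneuver-to-maneuver
    effort varies with CV ``maneuver_cv`` (lognormal). With
    ``generate_traces=False`` only subject-level ground truths are drawn
    (cheap, for distributional checks on large n).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    cal = cal or default_calibration()
    rng = _as_rng(seed)

    if group_mix is None:
        group_mix = {"control": 14, "asthma": 17, "COPD": 12}
    if isinstance(group_mix, str):
        group_mix = {group_mix: 1.0}
    groups = list(group_mix)
    weights = np.array([group_mix[g] for g in groups], dtype=float)
    weights /= weights.sum()
    # deterministic proportional allocation, remainder to the largest groups
    counts = np.floor(weights * n_subjects).astype(int)
    for i in np.argsort(-(weights * n_subjects - counts))[: n_subjects - counts.sum()]:
        counts[i] += 1

    subjects: list[CohortSubject] = []
    sid = 0
    for g, cnt in zip(groups, counts):
        for _ in range(cnt):
            sid += 1
            params = draw_subject_truth(g, rng)
            subj = CohortSubject(subject_id=f"S{sid:03d}", group=g, params=params)
            if generate_traces:
                for dev in ("a", "b"):
                    dev_cal = (
                        cal.perturbed(calibration_jitter, rng)
                        if calibration_jitter > 0 else cal
                    )
                    script = SessionScript(
                        subject_group=g,
                        n_maneuvers=n_maneuvers,
                        rng_seed=int(rng.integers(2**31)),
                    )
                    sess = make_session(
                        script, params=params, cal=dev_cal,
                        maneuver_cv=maneuver_cv,
                    )
                    setattr(subj, f"session_{dev}", sess)
            subjects.append(subj)
    return subjects
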