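"""End-to-end paired-device benchmark pipeline.

Glue that chains the simulator, the analysis pipeline and the agreement
statistics: simulate a cohort on two virtual devices, analyse every session
with the *nominal* calibration (the simulated devices carry their own hidden
calibration jitter, as two physical units would), and assemble the long-format
measurement table the agreement model consumes.
"""

from __future__ import annotations

import pandas as pd

from .agreement_stats import AgreementResults, DeviceAgreement
from .device_model import SensorCalibration, default_calibration
from .simulate import CohortSubject, make_cohort
from .spiro_analysis import analyze_session

__all__ = ["cohort_long_table", "run_paired_benchmark"]


def cohort_long_table(
    subjects: list[CohortSubject],
    cal: SensorCalibration | None = None,
    metrics: tuple[str, ...] = ("fev1", "fvc", "pef"),
) -> pd.DataFrame:
    """Analyse every session of a simulated cohort into a long-format table
    with columns subject_id, group, device, maneuver_index, metric, value."""
    cal = cal or default_calibration()
    rows = []
    for subj in subjects:
        for device, sess in (("novel", subj.session_a), ("reference", subj.session_b)):
            if sess is None:
                raise ValueError("cohort was generated without traces")
            trace, _ = sess
            analysis = analyze_session(trace, cal)
            for i, res in enumerate(analysis.maneuvers, start=1):
                for metric in metrics:
                    rows.append({
                        "subject_id": subj.subject_id,
                        "group": subj.group,
                        "device": device,
                        "maneuver_index": i,
                        "metric": metric,
                        "value": getattr(res.metrics, metric),
                    })
    return pd.DataFrame(rows)


def run_paired_benchmark(
    n_subjects: int = 43,
    seed: int = 0,
    metric: str = "fev1",
    cal: SensorCalibration | None = None,
    **cohort_kwargs,
) -> tuple[AgreementResults, pd.DataFrame]:
    """Simulate and evaluate a full paired-device benchmark.

    Returns the fitted agreement results for ``metric`` plus the long table
    (so other metrics can be fitted without re-simulating).
    """
    cal = cal or default_calibration()
    subjects = make_cohort(n_subjects, seed=seed, cal=cal, **cohort_kwargs)
    table = cohort_long_table(subjects, cal)
    results = DeviceAgreement.from_dataframe(table, metric=metric).fit()
    return results, table
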