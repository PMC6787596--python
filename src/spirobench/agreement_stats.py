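"""Device-agreement statistics for paired spirometer benchmarking.

Benchmarks a novel device against a reference from paired per-maneuver values:

* Pearson product-moment correlation (two-sided p via the t-transform);
* Bland-Altman analysis: per-pair differences a − b summarised by their mean
  (bias) and 95% limits of agreement bias ± 1.96·SD (n − 1 denominator);
* fixed-effects two-factor ANOVA (device × health state) with interaction,
  type-II sums of squares for unbalanced cells;
* intra-participant correlations between repeated reading sets.

The module also exposes a small statsmodels-flavoured front end:
``DeviceAgreement.from_dataframe(long_df).fit()`` returns an
:class:`AgreementResults` carrying all of the above with a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UnbalancedDesignError, UndefinedCorrelationError

__all__ = [
    "PearsonResult",
    "BlandAltmanResult",
    "pearson",
    "bland_altman",
    "two_factor_anova",
    "repeated_reading_correlation",
    "DeviceAgreement",
    "AgreementResults",
    "plot_bland_altman",
    "plot_device_scatter",
]


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int
    means: np.ndarray
    diffs: np.ndarray

    @property
    def loa_halfwidth(self) -> float:
        return (self.loa_high - self.loa_low) / 2.0


def pearson(x, y) -> PearsonResult:
    """Pearson product-moment correlation with two-sided p (n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired series must have equal length")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the variables")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


def bland_altman(a, b, multiplier: float = 1.96) -> BlandAltmanResult:
    """Bland-Altman method comparison on paired values.

    Differences are a − b; bias is their mean and the limits of agreement are
    bias ± multiplier·SD (sample SD, n − 1). The 1.96 multiplier is the normal
    95% convention; it is a fixed factor, not a t-quantile.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need >= 2 pairs")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        sd_diff=sd,
        n=int(a.size),
        means=(a + b) / 2.0,
        diffs=diffs,
    )


def two_factor_anova(values, device_factor, group_factor) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction, type-II sums of squares.

    Returns a table indexed by "device", "group", "device:group", "residual"
    with columns sum_sq, df, F, p. A factor with a single level is dropped
    from the model with a warning (the design degenerates to one-way); an
    empty crossed cell raises :class:`UnbalancedDesignError` naming the cell.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "device": np.asarray(device_factor).astype(str),
        "group": np.asarray(group_factor).astype(str),
    })
    dev_levels = df["device"].unique()
    grp_levels = df["group"].unique()
    if len(dev_levels) >= 2 and len(grp_levels) >= 2:
        cells = df.groupby(["device", "group"], observed=True).size()
        for d in dev_levels:
            for g in grp_levels:
                if (d, g) not in cells.index:
                    raise UnbalancedDesignError(
                        f"empty cell: device={d!r}, group={g!r}"
                    )
        formula = "value ~ C(device) * C(group)"
    else:
        kept = "device" if len(dev_levels) >= 2 else "group"
        warnings.warn(
            f"factor with a single level dropped; fitting one-way ANOVA on {kept}",
            stacklevel=2,
        )
        formula = f"value ~ C({kept})"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 F on degenerate data
        model = ols(formula, data=df).fit()
        table = anova_lm(model, typ=2)

    rename = {
        "C(device)": "device",
        "C(group)": "group",
        "C(device):C(group)": "device:group",
        "Residual": "residual",
    }
    table = table.rename(index=rename).rename(
        columns={"PR(>F)": "p", "sum_sq": "sum_sq"}
    )
    # degenerate all-equal data: an effect with numerically-zero sum of
    # squares carries no signal -> define F = 0, p = 1
    scale = max(float(np.abs(np.asarray(values, dtype=float)).max()), 1.0)
    zero = (table["sum_sq"] < (1e-12 * scale) ** 2 * len(df)) & (table.index != "residual")
    table.loc[zero, "F"] = 0.0
    table.loc[zero, "p"] = 1.0
    return table


def repeated_reading_correlation(readings) -> dict[tuple[int, int], PearsonResult | None]:
    """Pairwise Pearson r between reading sets of a subject × reading matrix.

    Missing readings (NaN) are pairwise-deleted; a pair with fewer than three
    complete subjects is reported as None (unavailable).
    """
    m = np.asarray(readings, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D subject × reading matrix with >= 2 columns")
    if m.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    out: dict[tuple[int, int], PearsonResult | None] = {}
    for i, j in combinations(range(m.shape[1]), 2):
        ok = ~(np.isnan(m[:, i]) | np.isnan(m[:, j]))
        if ok.sum() < 3:
            out[(i + 1, j + 1)] = None
            continue
        try:
            out[(i + 1, j + 1)] = pearson(m[ok, i], m[ok, j])
        except UndefinedCorrelationError:
            out[(i + 1, j + 1)] = None
    return out


# ---------------------------------------------------------------------------
# model-style front end
# ---------------------------------------------------------------------------

@dataclass
class AgreementResults:
    """Fitted paired-device agreement statistics.

    Attributes mirror the underlying primitives; ``summary()`` renders a
    compact report table.
    """

    metric_name: str
    device_names: tuple[str, str]
    n_pairs: int
    n_excluded: int
    pearson: PearsonResult
    bland_altman: BlandAltmanResult
    anova_table: pd.DataFrame
    mean_sem: dict[str, tuple[float, float]]
    anova_mode: str

    def summary(self) -> str:
        a, b = self.device_names
        ba = self.bland_altman
        lines = [
            f"Device agreement: {self.metric_name}  ({a} vs {b})",
            "=" * 58,
            f"paired values        {self.n_pairs}   (excluded incomplete: {self.n_excluded})",
            f"Pearson r            {self.pearson.r:8.4f}   p = {self.pearson.p:.3g}",
            f"bias ({a} - {b})     {ba.bias:8.4f}",
            f"95% LoA              [{ba.loa_low:8.4f}, {ba.loa_high:8.4f}]",
        ]
        for dev, (mean, sem) in self.mean_sem.items():
            lines.append(f"mean ± SEM [{dev}]     {mean:.3f} ± {sem:.3f}")
        lines.append(f"two-factor ANOVA ({self.anova_mode}):")
        for row in self.anova_table.index:
            if row == "residual":
                continue
            F = self.anova_table.loc[row, "F"]
            p = self.anova_table.loc[row, "p"]
            lines.append(f"  {row:<14} F = {F:7.3f}   p = {p:.3g}")
        return "\n".join(lines)


class DeviceAgreement:
    """Paired-device agreement model over a long-format measurement table.

    Expected columns: subject_id, group, device, maneuver_index, metric,
    value. Maneuver i on device A is paired with maneuver i on device B;
    incomplete pairs are excluded and counted.

    Examples
    --------
    >>> model = DeviceAgreement.from_dataframe(df, metric="fev1")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    REQUIRED = ("subject_id", "group", "device", "maneuver_index", "metric", "value")

    def __init__(self, data: pd.DataFrame, metric: str, devices: tuple[str, str]):
        self.data = data
        self.metric = metric
        self.devices = devices

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        metric: str | None = None,
        devices: tuple[str, str] | None = None,
    ) -> "DeviceAgreement":
        missing = [c for c in cls.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"long-format table missing columns: {missing}")
        if metric is None:
            metrics = df["metric"].unique()
            if len(metrics) != 1:
                raise ValueError(f"specify metric; table holds {sorted(metrics)}")
            metric = str(metrics[0])
        sub = df[df["metric"] == metric].copy()
        if devices is None:
            levels = sorted(sub["device"].unique())
            if len(levels) != 2:
                raise ValueError(f"need exactly 2 devices, found {levels}")
            devices = (levels[0], levels[1])
        return cls(sub, metric, devices)

    def fit(
        self,
        loa_multiplier: float = 1.96,
        anova_mode: str = "per_maneuver",
    ) -> AgreementResults:
        """Compute all agreement statistics.

        ``anova_mode`` is "per_maneuver" (each maneuver an observation) or
        "per_subject_mean" (maneuvers averaged within subject first).
        """
        a_name, b_name = self.devices
        wide = self.data.pivot_table(
            index=["subject_id", "group", "maneuver_index"],
            columns="device", values="value", aggfunc="first",
        )
        for dev in self.devices:
            if dev not in wide.columns:
                raise ValueError(f"device {dev!r} absent from table")
        complete = wide.dropna(subset=list(self.devices))
        n_excluded = len(wide) - len(complete)

        pr = pearson(complete[a_name], complete[b_name])
        ba = bland_altman(complete[a_name], complete[b_name], multiplier=loa_multiplier)

        if anova_mode == "per_subject_mean":
            anova_df = (
                self.data.groupby(["subject_id", "group", "device"], observed=True)["value"]
                .mean().reset_index()
            )
        elif anova_mode == "per_maneuver":
            anova_df = self.data.dropna(subset=["value"])
        else:
            raise ValueError("anova_mode must be 'per_maneuver' or 'per_subject_mean'")
        table = two_factor_anova(anova_df["value"], anova_df["device"], anova_df["group"])

        mean_sem = {}
        for dev in self.devices:
            vals = self.data.loc[self.data["device"] == dev, "value"].dropna()
            mean_sem[dev] = (float(vals.mean()), float(vals.sem()))

        return AgreementResults(
            metric_name=self.metric,
            device_names=self.devices,
            n_pairs=len(complete),
            n_excluded=n_excluded,
            pearson=pr,
            bland_altman=ba,
            anova_table=table,
            mean_sem=mean_sem,
            anova_mode=anova_mode,
        )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_bland_altman(result: BlandAltmanResult, ax=None, title: str | None = None):
    """Difference-vs-mean scatter with bias (dashed) and LoA (dotted) lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.diffs, s=12, alpha=0.7)
    ax.axhline(result.bias, linestyle="--", color="k", label=f"bias {result.bias:.3f}")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, linestyle=":", color="k")
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference (a − b)")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_device_scatter(a, b, ax=None, labels=("device a", "device b")):
    """Paired-value scatter with the identity line."""
    import matplotlib.pyplot as plt

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(b, a, s=12, alpha=0.7)
    lim = [min(a.min(), b.min()), max(a.max(), b.max())]
    ax.plot(lim, lim, "k--", linewidth=1)
    ax.set_xlabel(labels[1])
    ax.set_ylabel(labels[0])
    return ax
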