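"""Exponential growth-rate fitting and the relative salinity-sensitivity
statistic.

Growth is monitored as chlorophyll-a fluorescence sampled every 24 h over a
salinity panel (default 0.2, 0.6, 1.2, 1.8, 2.5, 3.3 % NaCl, four replicates).
The maximal growth rate mu_max (per day) is fitted on the exponential phase:
over all contiguous windows of at least four points, log-fluorescence is
regressed on time, and the steepest slope among windows whose coefficient of
determination reaches the quality gate (default R^2 >= 0.95) is kept.

Salinity sensitivity of a strain is the decline of mu_max from the optimal
range (0.2 or 0.6 %) to the pessimal range (1.8, 2.5 or 3.3 %), expressed as
a percentage of the most sensitive (reference) strain's decline, so the
reference scores exactly 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UndefinedSensitivityError, UsageError

DEFAULT_SALINITIES = (0.2, 0.6, 1.2, 1.8, 2.5, 3.3)
OPTIMAL_SALINITIES = (0.2, 0.6)
PESSIMAL_SALINITIES = (1.8, 2.5, 3.3)


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate's fluorescence time series at one salinity."""

    strain_id: str
    salinity: float
    replicate: int
    times_h: tuple[float, ...]
    fluorescence: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.fluorescence):
            raise DataError("times and fluorescence differ in length")
        if len(self.times_h) < 4:
            raise DataError("growth curve needs at least 4 points")
        if any(t2 <= t1 for t1, t2 in zip(self.times_h, self.times_h[1:])):
            raise DataError("times must be strictly increasing")
        if any(f <= 0 for f in self.fluorescence):
            raise DataError("fluorescence must be positive")


@dataclass(frozen=True)
class RateFit:
    """Fitted maximal rate with the window and fit quality it came from."""

    mu_per_day: float
    window: tuple[int, int] | None  # inclusive indices into the series
    r_squared: float | None
    no_growth: bool


def _window_fit(times_h: np.ndarray, log_f: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(times_h, log_f, 1)
    predicted = slope * times_h + intercept
    ss_res = float(np.sum((log_f - predicted) ** 2))
    ss_tot = float(np.sum((log_f - log_f.mean()) ** 2))
    if ss_tot < 1e-12:
        r2 = 1.0 if ss_res < 1e-12 else 0.0  # flat series: perfect flat fit
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), r2


def fit_exponential_rate(
    curve: GrowthCurve, min_points: int = 4, r2_gate: float = 0.95
) -> RateFit:
    """Maximal per-day rate over all well-fitting exponential windows.

    Windows are contiguous runs of ``min_points`` or more samples; each is
    fitted by least squares on log-fluorescence.  The steepest positive slope
    among windows passing the R^2 gate wins.  If no window qualifies (or the
    best qualifying slope is non-positive) the result is a flagged no-growth
    rate of zero rather than an exception.
    """
    if min_points < 3:
        raise UsageError("window needs at least 3 points for a meaningful fit")
    times = np.asarray(curve.times_h, dtype=float)
    log_f = np.log(np.asarray(curve.fluorescence, dtype=float))
    n = len(times)
    best: tuple[float, float, tuple[int, int]] | None = None
    for i in range(n - min_points + 1):
        for j in range(i + min_points - 1, n):
            slope, r2 = _window_fit(times[i : j + 1], log_f[i : j + 1])
            if r2 + 1e-12 < r2_gate:
                continue
            if best is None or slope > best[0]:
                best = (slope, r2, (i, j))
    if best is None or best[0] <= 0:
        return RateFit(0.0, None, None, no_growth=True)
    slope, r2, window = best
    return RateFit(slope * 24.0, window, r2, no_growth=False)


def mu_max_table(
    curves: Sequence[GrowthCurve], min_points: int = 4, r2_gate: float = 0.95
) -> pd.DataFrame:
    """Per-strain, per-salinity mu_max: median of the replicate fits."""
    rows = []
    for curve in curves:
        fit = fit_exponential_rate(curve, min_points, r2_gate)
        rows.append(
            {
                "strain_id": curve.strain_id,
                "salinity": curve.salinity,
                "replicate": curve.replicate,
                "mu_per_day": fit.mu_per_day,
            }
        )
    long = pd.DataFrame(rows)
    return (
        long.groupby(["strain_id", "salinity"])["mu_per_day"]
        .median()
        .unstack("salinity")
    )


@dataclass(frozen=True)
class SensitivityResult:
    strain_id: str
    mu_by_salinity: dict[float, float]
    decline: float
    sensitivity: float

    def __post_init__(self) -> None:
        if self.sensitivity < 0:
            raise DataError("sensitivity cannot be negative")


def salinity_sensitivity(
    rates: pd.DataFrame | Mapping[str, Mapping[float, float]],
    reference_id: str,
    optimal: Sequence[float] = OPTIMAL_SALINITIES,
    pessimal: Sequence[float] = PESSIMAL_SALINITIES,
) -> list[SensitivityResult]:
    """Relative salinity sensitivity, reference strain pinned to 100 %.

    decline(strain) = max mu over the optimal salinities minus min mu over
    the pessimal ones, floored at zero; sensitivity = 100 x decline /
    decline(reference).  The extremal reading covers the ambiguity of which
    optimal/pessimal condition anchors the decline.
    """
    if isinstance(rates, pd.DataFrame):
        table = {
            strain: {float(s): float(v) for s, v in row.dropna().items()}
            for strain, row in rates.iterrows()
        }
    else:
        table = {k: dict(v) for k, v in rates.items()}
    if reference_id not in table:
        raise UsageError(f"reference strain {reference_id!r} not in rate table")

    def decline(mu: Mapping[float, float]) -> float:
        opt = [mu[s] for s in optimal if s in mu]
        pess = [mu[s] for s in pessimal if s in mu]
        if not opt or not pess:
            raise DataError(
                "each strain needs a rate in both the optimal and pessimal range"
            )
        return max(0.0, max(opt) - min(pess))

    ref_decline = decline(table[reference_id])
    if ref_decline == 0:
        raise UndefinedSensitivityError(
            f"reference strain {reference_id!r} shows no decline; "
            "relative sensitivity is undefined"
        )
    return [
        SensitivityResult(
            strain_id=strain,
            mu_by_salinity=mu,
            decline=decline(mu),
            sensitivity=100.0 * decline(mu) / ref_decline,
        )
        for strain, mu in table.items()
    ]


def classify_salinity_response(
    sensitivity: float, cutoffs: tuple[float, float] = (33.0, 66.0)
) -> str:
    """Three response types by sensitivity percentage.

    The class names come from the observed growth phenotypes; the numeric
    boundaries are configuration defaults (no canonical values exist).
    """
    lo, hi = cutoffs
    if not (0 < lo < hi):
        raise UsageError(f"cutoffs {cutoffs} must be strictly increasing and positive")
    if sensitivity < 0:
        raise UsageError("sensitivity must be non-negative")
    if sensitivity < lo:
        return "robust"
    if sensitivity < hi:
        return "intermediately_sensitive"
    return "sensitive"


@dataclass(frozen=True)
class CellShapeSummary:
    """Box-and-whisker summary of cell length, width, and length:width ratio."""

    strain_id: str
    salinity: float
    length: dict[str, float]
    width: dict[str, float]
    ratio: dict[str, float]


def _box_stats(values: np.ndarray) -> dict[str, float]:
    q1, median, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(median),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": float(len(values) - len(inside)),
    }


def cell_shape_summary(
    strain_id: str,
    salinity: float,
    lengths_um: Sequence[float],
    widths_um: Sequence[float],
) -> CellShapeSummary:
    """Quartiles and 1.5xIQR whiskers for cell dimensions and their ratio.

    Outliers beyond the whiskers are excluded from the whisker range but
    remain in the data (they only affect the outlier count).
    """
    lengths = np.asarray(lengths_um, dtype=float)
    widths = np.asarray(widths_um, dtype=float)
    if len(lengths) != len(widths):
        raise DataError("length and width vectors differ in size")
    if len(lengths) < 5:
        raise DataError("need measurements for at least 5 cells")
    if (lengths <= 0).any() or (widths <= 0).any():
        raise DataError("cell measurements must be positive")
    return CellShapeSummary(
        strain_id=strain_id,
        salinity=salinity,
        length=_box_stats(lengths),
        width=_box_stats(widths),
        ratio=_box_stats(lengths / widths),
    )


def curves_from_frame(df: pd.DataFrame) -> list[GrowthCurve]:
    """Build curves from a long-format table (strain, salinity, replicate,
    time_h, fluorescence)."""
    required = {"strain_id", "salinity", "replicate", "time_h", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"growth table missing columns {sorted(missing)}")
    curves = []
    for (strain, salinity, replicate), grp in df.groupby(
        ["strain_id", "salinity", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain_id=str(strain),
                salinity=float(salinity),
                replicate=int(replicate),
                times_h=tuple(grp["time_h"].astype(float)),
                fluorescence=tuple(grp["fluorescence"].astype(float)),
            )
        )
    return curves
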