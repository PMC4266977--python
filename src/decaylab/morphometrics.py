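"""Percent-change morphometrics and linear regression of change on time.

During decay the body bloats and the trunk elongates, so linear dimensions
measured at sampling differ from the same dimension photographed at death.
Change is expressed as a percentage of the original dimension and regressed
on time (raw days); the F test of the regression slope asks whether a
proportion varies systematically with stage of decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import METRICS, MeasurementTable, ValidationError

__all__ = [
    "MeasurementChange",
    "RegressionReport",
    "percent_change",
    "compute_changes",
    "fit_change_regression",
    "fit_all_metrics",
    "slope_p_from_F",
    "f_from_r2",
]


@dataclass(frozen=True)
class MeasurementChange:
    specimen_id: str
    day: int
    metric: str
    change_percent: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.change_percent) or self.change_percent <= -100:
            raise ValidationError(
                f"change_percent must be finite and > -100, got {self.change_percent}"
            )


@dataclass(frozen=True)
class RegressionReport:
    """OLS fit of change (%) on day, with the slope F test.

    ``df`` is the (1, n-2) pair of the slope F test; the identity
    F = (R2 / (1 - R2)) * (n - 2) holds by construction.
    """

    metric: str
    n: int
    slope: float  # % per day
    intercept: float  # %
    r2: float
    F: float
    df: tuple[int, int]
    p: float


def percent_change(
    value_at_death: float, value_at_day: float, literal_sign: bool = False
) -> float:
    """Relative change of a dimension, as a percentage of its value at death.

    The default sign convention makes increases positive (decayed larger
    than original -> positive %), which is how elongation and bloating are
    naturally read.  ``literal_sign=True`` flips to
    (original - decayed)/original.
    """
    if value_at_death <= 0:
        raise ValidationError(f"value_at_death must be > 0, got {value_at_death}")
    change = 100.0 * (value_at_day - value_at_death) / value_at_death
    return -change if literal_sign else change


def compute_changes(
    table: MeasurementTable, literal_sign: bool = False
) -> list[MeasurementChange]:
    """Percent change for every record of a measurement table."""
    out = []
    for _, row in table.records.iterrows():
        out.append(
            MeasurementChange(
                specimen_id=row["specimen_id"],
                day=int(row["day"]),
                metric=row["metric"],
                change_percent=percent_change(
                    row["value_at_death"], row["value_at_day"], literal_sign
                ),
            )
        )
    return out


def fit_change_regression(changes: list[MeasurementChange]) -> RegressionReport:
    """OLS of change_percent on day for a single metric, with slope F test."""
    metrics = {c.metric for c in changes}
    if len(metrics) != 1:
        raise ValidationError(f"expected a single metric, got {sorted(metrics)}")
    (metric,) = metrics
    days = np.array([c.day for c in changes], dtype=float)
    y = np.array([c.change_percent for c in changes], dtype=float)
    n = len(y)
    if n < 3:
        raise ValidationError(f"need n >= 3 observations, got {n}")
    if np.unique(days).size < 2:
        raise ValidationError("all observations at the same day; slope undefined")
    fit = stats.linregress(days, y)
    # constant response: slope 0, nothing explained (linregress yields nan r)
    r2 = 0.0 if np.ptp(y) == 0 else float(fit.rvalue**2)
    df2 = n - 2
    F = f_from_r2(r2, df2)
    return RegressionReport(
        metric=metric,
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        F=F,
        df=(1, df2),
        p=slope_p_from_F(F, df2),
    )


def fit_all_metrics(
    table: MeasurementTable, literal_sign: bool = False
) -> list[RegressionReport]:
    """One independent regression per metric present in the table."""
    changes = compute_changes(table, literal_sign)
    by_metric: dict[str, list[MeasurementChange]] = {}
    for c in changes:
        by_metric.setdefault(c.metric, []).append(c)
    return [
        fit_change_regression(by_metric[m]) for m in METRICS if m in by_metric
    ]


def f_from_r2(r2: float, df2: int) -> float:
    """Slope F statistic implied by R^2 and residual df: F = R2/(1-R2) * df2."""
    if not 0 <= r2 <= 1:
        raise ValidationError(f"R^2 must lie in [0, 1], got {r2}")
    if r2 == 1:
        return np.inf
    return float(r2 / (1.0 - r2) * df2)


def slope_p_from_F(F: float, df2: int) -> float:
    """Upper-tail probability of F under the F(1, df2) null distribution.

    Identical to the two-sided p of the slope's t test, since t^2 on df2
    degrees of freedom is F(1, df2).
    """
    if F < 0:
        raise ValidationError(f"F must be non-negative, got {F}")
    if df2 < 1:
        raise ValidationError(f"df2 must be >= 1, got {df2}")
    return float(stats.f.sf(F, 1, df2))
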