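"""Goodness-of-fit statistics for measured-vs-calculated RLD comparisons.

Four statistics quantify how well a model's calculated RLD (``rld_c``)
matches the RLD measured on washed calibration cubes (``rld_m``):

* Nash-Sutcliffe efficiency NE = 1 - SSerr/SStot, in (-inf, 1], 1 ideal;
* normalized RMSE, in percent of the observed range (< 10% very good,
  > 25% poor);
* mean bias MB, in percent of the observed mean (negative means the
  model underestimates);
* index of agreement d, in [-1, 1], 1 ideal.

``validation_report`` assembles these, plus the slope/intercept/R^2 of
the calculated-on-measured regression, per (model, root class, variety)
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import fit_linear

__all__ = [
    "FitStatistics",
    "nash_efficiency",
    "nrmse",
    "mean_bias",
    "d_index",
    "fit_statistics",
    "validation_report",
    "round_report",
]


@dataclass(frozen=True)
class FitStatistics:
    """Validation statistics for one measured-vs-calculated comparison."""

    slope: float
    intercept: float
    r2: float
    nrmse: float  # percent
    mb: float  # percent, signed
    ne: float
    d: float
    n: int
    mean_measured: float
    mean_calculated: float


def _as_pair(rld_m: Sequence[float], rld_c: Sequence[float]):
    m = np.asarray(rld_m, dtype=float)
    c = np.asarray(rld_c, dtype=float)
    if m.shape != c.shape or m.ndim != 1:
        raise ValueError("rld_m and rld_c must be paired 1-D sequences")
    if len(m) < 2:
        raise ValueError("need at least two paired observations")
    return m, c


def nash_efficiency(rld_m: Sequence[float], rld_c: Sequence[float]) -> float:
    """Nash-Sutcliffe efficiency, 1 - SSerr/SStot.

    Equals 1 for a perfect fit and 0 when the predictions are no better
    than the observed mean; negative values mean the mean is the better
    predictor.
    """
    m, c = _as_pair(rld_m, rld_c)
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("undefined statistic: observed values are constant")
    ss_err = float(np.sum((c - m) ** 2))
    return (ss_tot - ss_err) / ss_tot


def nrmse(rld_m: Sequence[float], rld_c: Sequence[float], root: bool = True) -> float:
    """Normalized root-mean-square error in percent of the observed range.

    ``root=False`` exposes a no-radical variant (mean squared error over
    the range) for auditing; the default follows the statistic's name
    and takes the square root, so a perfect fit gives 0 either way.
    """
    m, c = _as_pair(rld_m, rld_c)
    rng = float(m.max() - m.min())
    if rng == 0:
        raise ValueError("undefined statistic: observed range is zero")
    mse = float(np.mean((c - m) ** 2))
    return 100.0 / rng * (np.sqrt(mse) if root else mse)


def mean_bias(rld_m: Sequence[float], rld_c: Sequence[float]) -> float:
    """Mean bias error in percent of the observed mean (signed).

    Negative values indicate the model underestimates the measurements.
    """
    m, c = _as_pair(rld_m, rld_c)
    mean_m = float(m.mean())
    if mean_m == 0:
        raise ValueError("undefined statistic: observed mean is zero")
    return 100.0 * float(np.sum(c - m)) / (len(m) * mean_m)


def d_index(rld_m: Sequence[float], rld_c: Sequence[float]) -> float:
    """Index of agreement, 1 - sum|c-m| / sum(|m-mean(c)| + |c-mean(c)|).

    Ranges over [-1, 1] with 1 indicating perfect agreement.  Both
    absolute-deviation terms in the denominator are taken about the mean
    of the *calculated* values (the convention used for the published
    validation tables; the classical index centers on the observed mean).
    """
    m, c = _as_pair(rld_m, rld_c)
    mean_c = float(c.mean())
    denom = float(np.sum(np.abs(m - mean_c) + np.abs(c - mean_c)))
    if denom == 0:
        raise ValueError("undefined statistic: all values identical")
    return 1.0 - float(np.sum(np.abs(c - m))) / denom


def fit_statistics(
    rld_m: Sequence[float],
    rld_c: Sequence[float],
    regress_calculated_on_measured: bool = True,
) -> FitStatistics:
    """All validation statistics for one paired sample.

    The regression line is calculated-on-measured by default (a slope
    above 1 then reads as mild overestimation); set the flag to False to
    regress measured on calculated instead.
    """
    m, c = _as_pair(rld_m, rld_c)
    if regress_calculated_on_measured:
        fit = fit_linear(m, c)
    else:
        fit = fit_linear(c, m)
    return FitStatistics(
        slope=fit.slope,
        intercept=fit.intercept,
        r2=fit.r2,
        nrmse=nrmse(m, c),
        mb=mean_bias(m, c),
        ne=nash_efficiency(m, c),
        d=d_index(m, c),
        n=len(m),
        mean_measured=float(m.mean()),
        mean_calculated=float(c.mean()),
    )


def validation_report(
    table: pd.DataFrame,
    group_keys: Optional[Sequence[str]] = ("model", "root_class", "variety"),
    measured_col: str = "rld_measured",
    calculated_col: str = "rld_calculated",
    min_group_size: int = 3,
    all_varieties_row: bool = True,
) -> pd.DataFrame:
    """Per-group validation statistics table.

    One row of :class:`FitStatistics` per group defined by
    ``group_keys`` (keys absent from the table are ignored), plus an
    all-varieties row per (model, root class) when varieties are
    grouped.  Groups smaller than ``min_group_size`` are skipped with a
    warning.
    """
    keys = [k for k in (group_keys or []) if k in table.columns]
    rows = []

    def stat_row(label: dict, sub: pd.DataFrame):
        if len(sub) < min_group_size:
            warnings.warn(
                f"group {label} has n={len(sub)} < {min_group_size}; skipped",
                stacklevel=2,
            )
            return
        stats = fit_statistics(
            sub[measured_col].to_numpy(), sub[calculated_col].to_numpy()
        )
        rows.append({**label, **asdict(stats)})

    if not keys:
        stat_row({}, table)
    else:
        for vals, sub in table.groupby(keys, dropna=False):
            if not isinstance(vals, tuple):
                vals = (vals,)
            stat_row(dict(zip(keys, vals)), sub)
        if all_varieties_row and "variety" in keys:
            outer = [k for k in keys if k != "variety"]
            if outer:
                for vals, sub in table.groupby(outer, dropna=False):
                    if not isinstance(vals, tuple):
                        vals = (vals,)
                    stat_row({**dict(zip(outer, vals)), "variety": "All var"}, sub)
            else:
                stat_row({"variety": "All var"}, table)
    return pd.DataFrame(rows)


def round_report(report: pd.DataFrame) -> pd.DataFrame:
    """Round a validation report for display.

    Two decimals for slope and R^2, three for d, integers for the NRMSE
    and MB percentages and the intercept; full precision is retained in
    the unrounded report.
    """
    out = report.copy()
    for col, nd in (("slope", 2), ("r2", 2), ("ne", 2), ("d", 3)):
        if col in out:
            out[col] = out[col].round(nd)
    for col in ("intercept", "nrmse", "mb"):
        if col in out:
            out[col] = out[col].round(0).astype(int)
    return out
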