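"""Dilution-series calibration and method comparison.

The benchmark: quantify every well of a dilution series with a chosen
method, regress the quantification metric against the known template amount
on a log-log scale (ordinary least squares, unweighted), and back-predict
an estimated amount for each well from the trend line.  For curve-fitting
methods the metric is the initial-amount estimate (log10-transformed); for
the Cq method the metric is the Cq itself, whose slope on near-ideal data
approaches -log2(10) ~ -3.32 cycles per decade.

Failed or degenerate wells are excluded with a recorded reason, never
imputed.  A per-series diagnostic regresses the fitted MAK2 ``k`` against
log10 of the known amount: mechanistically ``k`` should be constant for a
given amplicon/primer set, and a non-zero trend flags unexplained effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, InvalidParameterError, QPCRError
from .fitting import compute_cq, fit_exponential, fit_loglogistic, fit_mak2
from .preprocess import AmplificationCurve, estimate_baseline

__all__ = [
    "DilutionSeries",
    "CalibrationFit",
    "DilutionCalibrator",
    "KDiagnostic",
    "ComparisonReport",
    "METHODS",
    "quantify_curve",
    "calibrate_series",
    "k_dependence_diagnostic",
    "run_method_comparison",
    "plot_calibration",
]

logger = logging.getLogger("qpcrfit")

METHODS = ("mak2", "cq", "exponential", "loglogistic4", "loglogistic5")


@dataclass(frozen=True)
class DilutionSeries:
    """A collection of wells, each carrying its known template amount."""

    curves: list[AmplificationCurve]

    def known_levels(self) -> list[float]:
        return sorted({c.known_copies for c in self.curves if c.known_copies is not None})


@dataclass(frozen=True)
class CalibrationFit:
    """Log-log calibration of a quantification method on a dilution series.

    ``slope``/``intercept``/``r_squared`` describe the OLS fit of the metric
    (log10 estimate, or Cq) on log10(known copies).  ``estimated_copies``
    are the per-well back-predictions obtained by inverting the trend line.
    """

    method: str
    slope: float
    intercept: float
    r_squared: float
    n_used: int
    metrics: dict[str, float]
    known_copies: dict[str, float]
    estimated_copies: dict[str, float]
    excluded: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_used": self.n_used,
            "n_excluded": len(self.excluded),
        }


class DilutionCalibrator(BaseEstimator):
    """scikit-learn-style wrapper around the log-log calibration.

    ``fit(X, y)`` takes X = log10(known copies) (column vector) and y = the
    quantification metric; ``predict`` evaluates the trend line and
    ``inverse_predict`` maps metrics back to estimated copies.
    """

    def fit(self, X, y) -> "DilutionCalibrator":
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(np.unique(x)) < 2:
            raise InsufficientDataError("need >= 2 distinct dilution levels")
        res = linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.stderr_ = float(res.stderr)
        self.pvalue_ = float(res.pvalue)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x

    def inverse_predict(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float).reshape(-1)
        return (y - self.intercept_) / self.slope_


def quantify_curve(
    curve: AmplificationCurve, method: str, cq_threshold: float | None = None, **options
) -> float:
    """One curve's quantification metric under the chosen method.

    Returns the D0/F0 estimate for curve-fitting methods, or the Cq for the
    threshold method (``cq_threshold`` passes a dataset-wide absolute
    threshold through).
    """
    if method == "mak2":
        return float(fit_mak2(curve, **options).estimate_d0)
    if method == "cq":
        return float(compute_cq(curve, threshold=cq_threshold, **options).cq)
    if method == "exponential":
        return float(fit_exponential(curve, **options).estimate_d0)
    if method in ("loglogistic4", "loglogistic5"):
        n = 4 if method == "loglogistic4" else 5
        result = fit_loglogistic(curve, n_params=n, **options)
        if result.estimate_d0 is None:
            raise QPCRError(
                f"well {curve.well_id!r}: log-logistic fit yielded no usable F0 estimate"
            )
        return float(result.estimate_d0)
    raise InvalidParameterError(f"unknown method {method!r}; choose from {METHODS}")


def _dataset_threshold(series: DilutionSeries, threshold_fraction: float) -> float:
    """Dataset-wide Cq threshold: a fraction of the maximum adjusted signal."""
    max_adj = -np.inf
    for curve in series.curves:
        adj = curve.fluorescence - estimate_baseline(curve)
        max_adj = max(max_adj, float(np.max(adj)))
    return threshold_fraction * max_adj


def calibrate_series(
    series: DilutionSeries,
    method: str,
    threshold_fraction: float = 0.10,
    cq_threshold: float | None = None,
    **options,
) -> CalibrationFit:
    """Calibrate one method across a dilution series.

    Every well with known copies is quantified; wells whose fit fails are
    excluded with a logged reason.  Requires at least two usable distinct
    levels.  Back-predicted copies come from inverting the trend line, so
    perfectly proportional estimates reproduce the knowns exactly.
    """
    if method == "cq" and cq_threshold is None:
        cq_threshold = _dataset_threshold(series, threshold_fraction)
    metrics: dict[str, float] = {}
    knowns: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for curve in series.curves:
        if curve.known_copies is None:
            excluded[curve.well_id] = "no-known-copies"
            continue
        try:
            m = quantify_curve(curve, method, cq_threshold=cq_threshold, **options)
        except QPCRError as exc:
            reason = type(exc).__name__
            excluded[curve.well_id] = reason
            logger.info("excluding well %s from %s calibration: %s", curve.well_id, method, exc)
            continue
        if method != "cq" and not m > 0:
            excluded[curve.well_id] = "non-positive-estimate"
            continue
        metrics[curve.well_id] = m
        knowns[curve.well_id] = float(curve.known_copies)

    if len(set(knowns.values())) < 2:
        raise InsufficientDataError(
            f"method {method!r}: fewer than 2 usable dilution levels "
            f"({len(excluded)} wells excluded)"
        )
    wells = list(metrics)
    x = np.log10([knowns[w] for w in wells])
    y = np.array([metrics[w] for w in wells])
    if method != "cq":
        y = np.log10(y)
    cal = DilutionCalibrator().fit(x, y)
    estimated = 10.0 ** cal.inverse_predict(y)
    return CalibrationFit(
        method=method,
        slope=cal.slope_,
        intercept=cal.intercept_,
        r_squared=cal.r_squared_,
        n_used=len(wells),
        metrics=dict(metrics),
        known_copies=dict(knowns),
        estimated_copies=dict(zip(wells, (float(v) for v in estimated))),
        excluded=excluded,
    )


@dataclass(frozen=True)
class KDiagnostic:
    """Fitted MAK2 k per well and its trend against log10(known copies)."""

    per_curve: pd.DataFrame
    slope: float | None
    stderr: float | None
    pvalue: float | None


def k_dependence_diagnostic(series: DilutionSeries, **mak2_options) -> KDiagnostic:
    """Check whether fitted k drifts with template amount.

    Purely descriptive: reports the fitted k per well and, when at least two
    distinct levels with three wells fit successfully, the OLS slope of k
    against log10(known copies) with its standard error and p-value.
    """
    rows = []
    for curve in series.curves:
        if curve.known_copies is None:
            continue
        try:
            result = fit_mak2(curve, **mak2_options)
        except QPCRError as exc:
            logger.info("k-diagnostic: skipping well %s: %s", curve.well_id, exc)
            continue
        rows.append(
            {
                "well_id": curve.well_id,
                "known_copies": float(curve.known_copies),
                "k": result.params["k"],
                "d0": result.params["d0"],
            }
        )
    table = pd.DataFrame(rows, columns=["well_id", "known_copies", "k", "d0"])
    slope = stderr = pvalue = None
    if len(table) >= 3 and table["known_copies"].nunique() >= 2:
        res = linregress(np.log10(table["known_copies"]), table["k"])
        slope, stderr, pvalue = float(res.slope), float(res.stderr), float(res.pvalue)
    return KDiagnostic(per_curve=table, slope=slope, stderr=stderr, pvalue=pvalue)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-method calibrations plus a tidy per-well table."""

    calibrations: dict[str, CalibrationFit]
    failures: dict[str, str]
    table: pd.DataFrame

    def summary(self) -> dict:
        out = {m: cal.summary() for m, cal in self.calibrations.items()}
        for m, reason in self.failures.items():
            out[m] = {"method": m, "failed": reason}
        return out

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def run_method_comparison(
    series: DilutionSeries, methods=METHODS, **options
) -> ComparisonReport:
    """Run several quantification methods over one series.

    A method failing on all wells is reported as failed without aborting the
    rest.  The tidy table has one row per well per method.
    """
    calibrations: dict[str, CalibrationFit] = {}
    failures: dict[str, str] = {}
    rows = []
    for method in methods:
        try:
            cal = calibrate_series(series, method, **options)
        except QPCRError as exc:
            failures[method] = str(exc)
            logger.warning("method %s failed on the whole series: %s", method, exc)
            continue
        calibrations[method] = cal
        for well, metric in cal.metrics.items():
            rows.append(
                {
                    "well_id": well,
                    "method": method,
                    "known_copies": cal.known_copies[well],
                    "metric": metric,
                    "estimated_copies": cal.estimated_copies[well],
                    "status": "ok",
                    "reason": "",
                }
            )
        for well, reason in cal.excluded.items():
            rows.append(
                {
                    "well_id": well,
                    "method": method,
                    "known_copies": np.nan,
                    "metric": np.nan,
                    "estimated_copies": np.nan,
                    "status": "excluded",
                    "reason": reason,
                }
            )
    columns = ["well_id", "method", "known_copies", "metric", "estimated_copies", "status", "reason"]
    return ComparisonReport(
        calibrations=calibrations,
        failures=failures,
        table=pd.DataFrame(rows, columns=columns),
    )


def plot_calibration(report: ComparisonReport, path) -> None:
    """Log-log estimated-vs-known panels with the 45-degree agreement line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(report.calibrations)
    fig, axes = plt.subplots(1, max(len(methods), 1), figsize=(3.2 * max(len(methods), 1), 3.2))
    if len(methods) <= 1:
        axes = [axes]
    for ax, method in zip(axes, methods):
        cal = report.calibrations[method]
        known = np.array([cal.known_copies[w] for w in cal.metrics])
        est = np.array([cal.estimated_copies[w] for w in cal.metrics])
        ax.loglog(known, est, "o", ms=4)
        lims = [known.min(), known.max()]
        ax.loglog(lims, lims, "k-", lw=0.8)
        ax.set_title(f"{method} (R²={cal.r_squared:.3f})", fontsize=9)
        ax.set_xlabel("known")
    axes[0].set_ylabel("estimated")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
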