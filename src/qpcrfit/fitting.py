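"""Single-curve quantification methods.

Four ways to turn one amplification curve into an initial-amount estimate:

* :class:`MAK2Regressor` / :func:`fit_mak2` — fit the MAK2 recursion
  (D0, k, Fb) to the truncated exponential phase by Nelder-Mead on the sum
  of squared residuals; the fitted D0 is the estimate.
* :class:`CqEstimator` / :func:`compute_cq` — classic threshold method:
  the fractional cycle where background-adjusted fluorescence crosses a
  threshold (default ~10% of maximum signal), linearly interpolated.
* :class:`ExponentialRegressor` / :func:`fit_exponential` — constant-
  efficiency model F_n = Fb + F0*(1+E)^n fitted over the smallest early
  window that supports a genuinely nonlinear fit; F0 is the estimate.
* :class:`LogLogisticRegressor` / :func:`fit_loglogistic` — 4/5-parameter
  log-logistic sigmoid fitted to the full curve, with the initial
  fluorescence recovered by a second-stage exponential fit to the model's
  own exponential-phase predictions (:func:`estimate_f0_two_stage`).

All estimators follow the scikit-learn protocol: ``fit(X, y)`` with X the
cycle numbers (column vector) and y the fluorescence, fitted attributes
with trailing underscores, and ``predict(X)`` returning model fluorescence.
All fits are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
    NoAmplificationError,
    NoCrossingError,
)
from .mak2 import MAK2Params, simulate_trajectory
from .preprocess import (
    AmplificationCurve,
    estimate_baseline,
    find_truncation_cycle,
    finite_differences,
)

__all__ = [
    "FitResult",
    "CqResult",
    "MAK2Regressor",
    "ExponentialRegressor",
    "LogLogisticRegressor",
    "CqEstimator",
    "fit_mak2",
    "compute_cq",
    "fit_exponential",
    "fit_loglogistic",
    "estimate_f0_two_stage",
]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-curve model fit.

    ``params`` is the method-specific parameter dictionary, ``ssr`` the sum
    of squared residuals over ``cycles_used`` (inclusive 1-based range), and
    ``estimate_d0`` the initial-amount estimate in fluorescence units.
    """

    method: str
    params: dict
    ssr: float
    cycles_used: tuple[int, int]
    converged: bool
    n_iterations: int
    estimate_d0: float | None
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CqResult:
    """Fractional quantification cycle with the threshold/baseline used."""

    cq: float
    threshold: float
    baseline: float
    at_first_cycle: bool = False


def _curve_from_xy(X, y) -> AmplificationCurve:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise InvalidParameterError("X must be a single column of cycle numbers")
        X = X[:, 0]
    cycles = X.astype(int)
    if np.any(cycles != X):
        raise InvalidParameterError("cycle numbers must be integers")
    return AmplificationCurve(well_id="<xy>", cycles=cycles, fluorescence=np.asarray(y, dtype=float))


def _as_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[:, 0]
    return X


# ---------------------------------------------------------------------------
# MAK2


class MAK2Regressor(RegressorMixin, BaseEstimator):
    """Fit the MAK2 model (D0, k, Fb) to one amplification curve.

    The curve is truncated at the cycle of maximum slope increase (unless
    ``cutoff_cycle`` overrides it), and the SSR between ``Fb + D_n`` and the
    observed fluorescence is minimized by Nelder-Mead in
    ``(log10 D0, log10 k, Fb)`` — the log parameterization enforces
    positivity without constraints.  A small deterministic multi-start grid
    over log10 D0 (offsets relative to the maximum background-adjusted
    signal) guards against local minima; the best SSR wins.

    Parameters
    ----------
    max_iter : int
        Nelder-Mead iteration cap per start (default 5000).
    ssr_rtol : float
        Relative SSR spread for simplex convergence (default 1e-10).
    multistart_offsets : sequence of float
        log10(D0) starting offsets below the maximum adjusted signal.
    truncate : bool
        Apply the maximum-slope-increase truncation rule (default True).
    cutoff_cycle : int or None
        Explicit truncation cycle, overriding the rule (for robustness
        studies).
    min_cycles : int
        Minimum retained cycles required to attempt a fit.
    """

    def __init__(
        self,
        max_iter: int = 5000,
        ssr_rtol: float = 1e-10,
        multistart_offsets: Sequence[float] = (-2.0, -4.0, -6.0, -8.0),
        truncate: bool = True,
        cutoff_cycle: int | None = None,
        min_cycles: int = 5,
    ) -> None:
        self.max_iter = max_iter
        self.ssr_rtol = ssr_rtol
        self.multistart_offsets = multistart_offsets
        self.truncate = truncate
        self.cutoff_cycle = cutoff_cycle
        self.min_cycles = min_cycles

    def fit(self, X, y) -> "MAK2Regressor":
        curve = _curve_from_xy(X, y)
        return self.fit_curve(curve)

    def fit_curve(self, curve: AmplificationCurve) -> "MAK2Regressor":
        if self.cutoff_cycle is not None:
            cutoff = int(self.cutoff_cycle)
        elif self.truncate:
            trunc = find_truncation_cycle(curve)
            if trunc.flagged_degenerate:
                raise NoAmplificationError(
                    f"well {curve.well_id!r}: no growth detected (max slope increase <= 0)"
                )
            cutoff = trunc.cutoff_cycle
        else:
            cutoff = int(curve.cycles[-1])
        mask = curve.cycles <= cutoff
        cycles = curve.cycles[mask]
        yobs = curve.fluorescence[mask]
        baseline = estimate_baseline(curve)
        adjusted = yobs - baseline
        max_adj = float(np.max(adjusted))
        # a curve of pure noise around a constant has no business being fit:
        # require signal at least 5 baseline SDs above the baseline level
        n_base = min(max(3, len(cycles) - 2), len(curve))
        sd_base = float(np.std(curve.fluorescence[:n_base], ddof=1))
        if max_adj <= 5.0 * sd_base:
            raise NoAmplificationError(
                f"well {curve.well_id!r}: no signal above baseline noise in retained "
                f"cycles (max {max_adj:.3g} vs noise SD {sd_base:.3g})"
            )
        if len(cycles) < self.min_cycles:
            raise InsufficientDataError(
                f"well {curve.well_id!r}: only {len(cycles)} cycles retained "
                f"(cutoff {cutoff}); need >= {self.min_cycles}"
            )
        first, _ = finite_differences(curve)
        k0 = max(float(np.max(first)) / math.log(2.0), 1e-12)
        d0_heur = max(1e-4 * max_adj, 1e-300)

        n_sim = int(cycles[-1])
        idx = cycles - 1

        def ssr(x: np.ndarray) -> float:
            log10_d0 = min(max(x[0], -300.0), 300.0)
            log10_k = min(max(x[1], -300.0), 300.0)
            d0, k, fb = 10.0**log10_d0, 10.0**log10_k, x[2]
            d = np.empty(n_sim)
            cur = d0
            for i in range(n_sim):
                r = cur / k
                cur = cur + k * (math.log(r) if r > 1e15 else math.log1p(r))
                d[i] = cur
            resid = fb + d[idx] - yobs
            return float(resid @ resid)

        starts = [np.array([math.log10(d0_heur), math.log10(k0), baseline])]
        for off in self.multistart_offsets:
            starts.append(np.array([math.log10(max_adj) + off, math.log10(k0), baseline]))

        best = None
        total_iter = 0
        for x0 in starts:
            f0 = ssr(x0)
            res = minimize(
                ssr,
                x0,
                method="Nelder-Mead",
                options=dict(
                    maxiter=self.max_iter,
                    maxfev=2 * self.max_iter,
                    xatol=1e-9,
                    fatol=self.ssr_rtol * max(f0, 1e-30),
                ),
            )
            total_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res

        self.d0_ = float(10.0 ** best.x[0])
        self.k_ = float(10.0 ** best.x[1])
        self.fb_ = float(best.x[2])
        self.ssr_ = float(best.fun)
        self.converged_ = bool(best.success)
        self.n_iter_ = int(total_iter)
        self.cutoff_cycle_ = cutoff
        self.cycles_used_ = (int(cycles[0]), int(cycles[-1]))
        self.baseline_ = baseline
        return self

    def predict(self, X) -> np.ndarray:
        cyc = _as_X(X).astype(int)
        traj = simulate_trajectory(MAK2Params(self.d0_, self.k_, self.fb_), int(cyc.max()))
        return traj.f[cyc - 1]

    def result_(self) -> FitResult:
        return FitResult(
            method="mak2",
            params={"d0": self.d0_, "k": self.k_, "fb": self.fb_},
            ssr=self.ssr_,
            cycles_used=self.cycles_used_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            estimate_d0=self.d0_,
            diagnostics={"cutoff_cycle": self.cutoff_cycle_, "baseline": self.baseline_},
        )


def fit_mak2(curve: AmplificationCurve, **options) -> FitResult:
    """Fit MAK2 to a curve; see :class:`MAK2Regressor` for options."""
    return MAK2Regressor(**options).fit_curve(curve).result_()


# ---------------------------------------------------------------------------
# Cq


class CqEstimator(BaseEstimator):
    """Fractional-cycle threshold quantification.

    The threshold defaults to ``threshold_fraction`` of the curve's maximum
    background-adjusted signal (about 10% mirrors common practice); an
    absolute ``threshold`` — e.g. a dataset-wide one — overrides the
    fraction.  The Cq is found by linear interpolation between the last
    cycle below and the first cycle at or above the threshold.
    """

    def __init__(
        self,
        threshold_fraction: float = 0.10,
        threshold: float | None = None,
        baseline: float | None = None,
        baseline_cycles: int | None = None,
    ) -> None:
        self.threshold_fraction = threshold_fraction
        self.threshold = threshold
        self.baseline = baseline
        self.baseline_cycles = baseline_cycles

    def fit(self, X, y) -> "CqEstimator":
        return self.fit_curve(_curve_from_xy(X, y))

    def fit_curve(self, curve: AmplificationCurve) -> "CqEstimator":
        if self.threshold is None and not (0.0 < self.threshold_fraction < 1.0):
            raise InvalidParameterError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction!r}"
            )
        baseline = (
            self.baseline
            if self.baseline is not None
            else estimate_baseline(curve, self.baseline_cycles)
        )
        adjusted = curve.fluorescence - baseline
        threshold = (
            self.threshold
            if self.threshold is not None
            else self.threshold_fraction * float(np.max(adjusted))
        )
        if threshold <= 0:
            raise NoCrossingError(
                f"well {curve.well_id!r}: non-positive threshold {threshold!r}"
            )
        above = np.flatnonzero(adjusted >= threshold)
        if above.size == 0:
            raise NoCrossingError(
                f"well {curve.well_id!r}: signal never reaches threshold {threshold:.4g}"
            )
        i = int(above[0])
        if i == 0:
            cq = float(curve.cycles[0])
            at_first = True
        else:
            c0, c1 = float(curve.cycles[i - 1]), float(curve.cycles[i])
            a0, a1 = float(adjusted[i - 1]), float(adjusted[i])
            cq = c0 + (threshold - a0) / (a1 - a0) * (c1 - c0)
            at_first = False
        self.cq_ = cq
        self.threshold_ = float(threshold)
        self.baseline_ = float(baseline)
        self.at_first_cycle_ = at_first
        return self

    def result_(self) -> CqResult:
        return CqResult(
            cq=self.cq_,
            threshold=self.threshold_,
            baseline=self.baseline_,
            at_first_cycle=self.at_first_cycle_,
        )


def compute_cq(
    curve: AmplificationCurve,
    threshold_fraction: float = 0.10,
    threshold: float | None = None,
    baseline: float | None = None,
    baseline_cycles: int | None = None,
) -> CqResult:
    """Fractional quantification cycle of one curve; see :class:`CqEstimator`."""
    est = CqEstimator(threshold_fraction, threshold, baseline, baseline_cycles)
    return est.fit_curve(curve).result_()


# ---------------------------------------------------------------------------
# Exponential


def _exp_model(n: np.ndarray, fb: float, e: float, f0: float) -> np.ndarray:
    return fb + f0 * (1.0 + e) ** n


class ExponentialRegressor(RegressorMixin, BaseEstimator):
    """Constant-efficiency exponential fit, F_n = Fb + F0*(1+E)^n.

    The fitting window expands cycle by cycle from cycle 1 and the first
    window is accepted whose fit converges with efficiency above
    ``efficiency_floor`` and with genuine curvature (SSR improvement over a
    straight-line fit of more than ``curvature_gain``); the window never
    extends past the truncation cycle.  This operationalizes "the minimum
    amount of data, beginning with cycle 1, that supports a nonlinear fit".
    """

    def __init__(
        self,
        min_window: int = 5,
        efficiency_floor: float = 0.01,
        curvature_gain: float = 0.05,
        max_nfev: int = 20000,
    ) -> None:
        self.min_window = min_window
        self.efficiency_floor = efficiency_floor
        self.curvature_gain = curvature_gain
        self.max_nfev = max_nfev

    def fit(self, X, y) -> "ExponentialRegressor":
        return self.fit_curve(_curve_from_xy(X, y))

    def fit_curve(self, curve: AmplificationCurve) -> "ExponentialRegressor":
        trunc = find_truncation_cycle(curve)
        if trunc.flagged_degenerate:
            raise FitFailureError(
                f"well {curve.well_id!r}: no growth detected; exponential fit impossible"
            )
        cap_pos = int(np.searchsorted(curve.cycles, trunc.cutoff_cycle)) + 1
        baseline = estimate_baseline(curve)
        cycles = curve.cycles.astype(float)
        yobs = curve.fluorescence
        nfev_total = 0

        for w in range(max(self.min_window, 4), cap_pos + 1):
            cw, yw = cycles[:w], yobs[:w]
            # heuristic start: efficiency from the last pair of increments
            d1, d2 = yw[-2] - yw[-3], yw[-1] - yw[-2]
            e0 = min(max(d2 / d1 - 1.0, 0.1, self.efficiency_floor), 1.0) if d1 > 0 else 0.9
            adj_last = max(yw[-1] - baseline, 1e-12)
            f00 = adj_last / (1.0 + e0) ** cw[-1]

            def resid(p: np.ndarray) -> np.ndarray:
                return _exp_model(cw, p[0], p[1], p[2]) - yw

            try:
                res = least_squares(
                    resid,
                    np.array([baseline, e0, f00]),
                    bounds=([-np.inf, 1e-6, 1e-300], [np.inf, 10.0, np.inf]),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=self.max_nfev,
                )
            except ValueError:
                continue
            nfev_total += res.nfev
            if res.status <= 0 or not np.all(np.isfinite(res.x)):
                continue
            fb, e, f0 = res.x
            if e <= self.efficiency_floor or f0 <= 0:
                continue
            ssr_exp = float(2.0 * res.cost)
            line = np.polynomial.polynomial.polyfit(cw, yw, 1)
            resid_line = yobs[:w] - np.polynomial.polynomial.polyval(cw, line)
            ssr_line = float(resid_line @ resid_line)
            if ssr_exp >= (1.0 - self.curvature_gain) * ssr_line:
                continue
            self.fb_, self.e_, self.f0_ = float(fb), float(e), float(f0)
            self.ssr_ = ssr_exp
            self.window_ = (int(curve.cycles[0]), int(curve.cycles[w - 1]))
            self.converged_ = True
            self.n_iter_ = int(nfev_total)
            return self

        raise FitFailureError(
            f"well {curve.well_id!r}: no window up to cycle {trunc.cutoff_cycle} "
            "yielded a converged, curvature-bearing exponential fit"
        )

    def predict(self, X) -> np.ndarray:
        return _exp_model(_as_X(X), self.fb_, self.e_, self.f0_)

    def result_(self) -> FitResult:
        return FitResult(
            method="exponential",
            params={"fb": self.fb_, "e": self.e_, "f0": self.f0_},
            ssr=self.ssr_,
            cycles_used=self.window_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            estimate_d0=self.f0_,
        )


def fit_exponential(curve: AmplificationCurve, **options) -> FitResult:
    """Exponential fit of a curve; see :class:`ExponentialRegressor`."""
    return ExponentialRegressor(**options).fit_curve(curve).result_()


# ---------------------------------------------------------------------------
# Log-logistic


def _ll_model(
    n: np.ndarray, fb: float, fmax: float, b: float, e: float, f: float
) -> np.ndarray:
    z = b * (np.log(n) - math.log(e))
    # 1/(1+exp(z))**f computed as exp(-f*softplus(z)) to avoid overflow
    softplus = np.where(z > 30.0, z, np.log1p(np.exp(np.minimum(z, 30.0))))
    return fb + (fmax - fb) * np.exp(-f * softplus)


class LogLogisticRegressor(RegressorMixin, BaseEstimator):
    """4/5-parameter log-logistic sigmoid fit to the full curve.

    Model: ``F(n) = Fb + (Fmax - Fb) / (1 + exp(b*(ln n - ln e)))**f`` with
    ``f`` fixed to 1 in the 4-parameter case; ``f`` accounts for asymmetry.
    The whole curve, plateau included, is used — Fmax is meaningless on
    truncated data.  The initial-amount estimate is produced by the
    two-stage procedure (:func:`estimate_f0_two_stage`).

    Ill-conditioning (column-scaled Jacobian condition number above
    ``cond_max``) is flagged via ``ill_conditioned_``, as happens on curves
    without a plateau.
    """

    def __init__(
        self,
        n_params: int = 5,
        max_nfev: int = 50000,
        cond_max: float = 1e8,
        two_stage_estimate: bool = True,
    ) -> None:
        self.n_params = n_params
        self.max_nfev = max_nfev
        self.cond_max = cond_max
        self.two_stage_estimate = two_stage_estimate

    def fit(self, X, y) -> "LogLogisticRegressor":
        return self.fit_curve(_curve_from_xy(X, y))

    def fit_curve(self, curve: AmplificationCurve) -> "LogLogisticRegressor":
        if self.n_params not in (4, 5):
            raise InvalidParameterError(f"n_params must be 4 or 5, got {self.n_params!r}")
        cycles = curve.cycles.astype(float)
        yobs = curve.fluorescence
        self.cycles_used_ = (int(curve.cycles[0]), int(curve.cycles[-1]))
        fb0 = float(np.min(yobs))
        fmax0 = float(np.max(yobs))
        if fmax0 <= fb0:
            raise FitFailureError(f"well {curve.well_id!r}: flat curve")
        half = fb0 + 0.5 * (fmax0 - fb0)
        e0 = float(cycles[int(np.argmin(np.abs(yobs - half)))])
        fixed_f = self.n_params == 4

        def unpack(p: np.ndarray) -> tuple[float, float, float, float, float]:
            if fixed_f:
                return p[0], p[1], p[2], p[3], 1.0
            return p[0], p[1], p[2], p[3], p[4]

        def resid(p: np.ndarray) -> np.ndarray:
            return _ll_model(cycles, *unpack(p)) - yobs

        p0 = [fb0, fmax0, -8.0, max(e0, 1.0)]
        lower = [-np.inf, -np.inf, -1e3, 1e-6]
        upper = [np.inf, np.inf, 1e3, 1e6]
        if not fixed_f:
            p0.append(1.0)
            lower.append(1e-3)
            upper.append(1e3)
        res = least_squares(
            resid,
            np.array(p0),
            bounds=(lower, upper),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=self.max_nfev,
        )
        fb, fmax, b, e, f = unpack(res.x)
        self.fb_, self.fmax_ = float(fb), float(fmax)
        self.b_, self.e_, self.f_ = float(b), float(e), float(f)
        self.ssr_ = float(2.0 * res.cost)
        self.converged_ = bool(res.status > 0 and np.all(np.isfinite(res.x)))
        self.n_iter_ = int(res.nfev)
        norms = np.linalg.norm(res.jac, axis=0)
        norms[norms == 0] = 1.0
        cond = float(np.linalg.cond(res.jac / norms))
        self.condition_number_ = cond
        # relative standard error of Fmax from the asymptotic covariance:
        # curves without a plateau leave Fmax essentially unconstrained
        dof = max(len(yobs) - len(res.x), 1)
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * (2.0 * res.cost / dof)
            se_fmax = math.sqrt(max(cov[1, 1], 0.0))
            self.rse_fmax_ = se_fmax / abs(fmax) if fmax != 0 else math.inf
        except np.linalg.LinAlgError:
            self.rse_fmax_ = math.inf
        self.ill_conditioned_ = (
            not np.isfinite(cond)
            or cond > self.cond_max
            or not np.isfinite(self.rse_fmax_)
            or self.rse_fmax_ > 0.25
        )
        if not self.converged_:
            raise FitFailureError(
                f"well {curve.well_id!r}: log-logistic fit did not converge "
                f"(status {res.status}, nfev {res.nfev})"
            )
        self.estimate_d0_ = None
        if self.two_stage_estimate and not self.ill_conditioned_:
            try:
                self.estimate_d0_ = estimate_f0_two_stage(self.result_(), curve)
            except FitFailureError:
                self.estimate_d0_ = None
        return self

    def predict(self, X) -> np.ndarray:
        return _ll_model(_as_X(X), self.fb_, self.fmax_, self.b_, self.e_, self.f_)

    def result_(self) -> FitResult:
        return FitResult(
            method=f"loglogistic{self.n_params}",
            params={
                "fb": self.fb_,
                "fmax": self.fmax_,
                "b": self.b_,
                "e": self.e_,
                "f": self.f_,
            },
            ssr=self.ssr_,
            cycles_used=self.cycles_used_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
            estimate_d0=getattr(self, "estimate_d0_", None),
            diagnostics={
                "condition_number": self.condition_number_,
                "rse_fmax": self.rse_fmax_,
                "ill_conditioned": self.ill_conditioned_,
            },
        )


def fit_loglogistic(curve: AmplificationCurve, n_params: int = 5, **options) -> FitResult:
    """Log-logistic fit of a full curve; see :class:`LogLogisticRegressor`."""
    return LogLogisticRegressor(n_params=n_params, **options).fit_curve(curve).result_()


def estimate_f0_two_stage(
    ll_fit: FitResult,
    curve: AmplificationCurve,
    takeoff_fraction: float = 0.005,
    min_points: int = 4,
) -> float:
    """Initial fluorescence from a fitted log-logistic model.

    Stage two of sigmoid-based quantification: evaluate the fitted
    log-logistic model over the curve's cycles and fit the constant-
    efficiency exponential model to the predictions over the exponential-
    phase window — from the takeoff (where the background-adjusted
    prediction first reaches ``takeoff_fraction`` of its value at the
    maximum-slope-increase cycle) up to that cycle.  The sub-fit's F0 is
    the estimate.  Cycles before takeoff are excluded deliberately: there
    the sigmoid's tail follows a power law in cycle number, not the
    reaction's exponential growth, and would corrupt the estimate.
    """
    if not ll_fit.converged:
        raise FitFailureError("log-logistic fit did not converge; no F0 estimate")
    p = ll_fit.params
    cyc = curve.cycles.astype(float)
    predicted = _ll_model(cyc, p["fb"], p["fmax"], p["b"], p["e"], p["f"])
    pseudo = AmplificationCurve(
        well_id=f"{curve.well_id}:llpred",
        cycles=curve.cycles,
        fluorescence=predicted,
        known_copies=curve.known_copies,
    )
    trunc = find_truncation_cycle(pseudo)
    if trunc.flagged_degenerate:
        raise FitFailureError(
            f"well {curve.well_id!r}: fitted log-logistic model shows no growth phase"
        )
    end = int(np.searchsorted(curve.cycles, trunc.cutoff_cycle)) + 1
    adjusted = predicted - p["fb"]
    ref = adjusted[end - 1]
    if ref <= 0:
        raise FitFailureError(f"well {curve.well_id!r}: no signal in the model predictions")
    above = np.flatnonzero(adjusted[:end] >= takeoff_fraction * ref)
    start = int(above[0]) if above.size else 0
    if end - start < min_points:
        start = max(0, end - min_points)
    if end - start < min_points:
        raise FitFailureError(
            f"well {curve.well_id!r}: exponential-phase window too short "
            f"({end - start} points)"
        )
    cw, yw = cyc[start:end], predicted[start:end]

    # start values from the window's endpoint growth ratio
    ratio = (yw[-1] - p["fb"]) / max(yw[-2] - p["fb"], 1e-300)
    e0 = min(max(ratio - 1.0, 0.05), 5.0)
    f00 = max((yw[-1] - p["fb"]) / (1.0 + e0) ** cw[-1], 1e-300)

    def resid(q: np.ndarray) -> np.ndarray:
        return _exp_model(cw, q[0], q[1], q[2]) - yw

    res = least_squares(
        resid,
        np.array([p["fb"], e0, f00]),
        bounds=([-np.inf, 1e-6, 1e-300], [np.inf, 10.0, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=20000,
    )
    if res.status <= 0 or not np.all(np.isfinite(res.x)) or res.x[2] <= 0:
        raise FitFailureError(
            f"well {curve.well_id!r}: exponential sub-fit of the log-logistic "
            "predictions failed"
        )
    return float(res.x[2])
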