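"""Single-curve quantification: MAK2 fitting, Cq, exponential, log-logistic."""

import math

import numpy as np
import pytest

from qpcrfit import (
    AmplificationCurve,
    FitFailureError,
    MAK2Params,
    MAK2Regressor,
    NoAmplificationError,
    NoCrossingError,
    compute_cq,
    fit_exponential,
    fit_loglogistic,
    fit_mak2,
    simulate_trajectory,
)
from qpcrfit.fitting import _exp_model, _ll_model
from qpcrfit.simulate import GeneratorConfig, generate_curve

from conftest import make_curve


# ---------------------------------------------------------------------------
# MAK2


def test_mak2_round_trip_on_pure_model_data():
    traj = simulate_trajectory(MAK2Params(1e-4, 0.05, 1.0), 30)
    res = fit_mak2(make_curve(traj.f))
    assert abs(math.log10(res.estimate_d0) + 4.0) < 0.02
    assert res.params["k"] == pytest.approx(0.05, rel=0.01)
    assert res.params["fb"] == pytest.approx(1.0, abs=0.01)
    assert res.ssr < 1e-6
    assert res.estimate_d0 > 0 and res.params["k"] > 0


def test_mak2_round_trip_with_noise():
    rng = np.random.default_rng(42)
    traj = simulate_trajectory(MAK2Params(1e-4, 0.05, 1.0), 30)
    res = fit_mak2(make_curve(traj.f + rng.normal(0, 0.005, 30)))
    assert abs(math.log10(res.estimate_d0) + 4.0) < 0.3


def test_mak2_rejects_pure_noise():
    rng = np.random.default_rng(0)
    with pytest.raises(NoAmplificationError):
        fit_mak2(make_curve(1.0 + rng.normal(0, 0.01, 40)))


def test_mak2_recovery_across_decades(noiseless_config):
    """Initial amounts spanning the dilution range are recovered at every
    level from plateau-bearing synthetic curves."""
    for level in range(len(noiseless_config.d0_levels)):
        curve, truth = generate_curve(noiseless_config, level)
        res = fit_mak2(curve)
        assert abs(math.log10(res.estimate_d0 / truth["d0"])) < 0.05
        assert res.params["k"] == pytest.approx(truth["k"], rel=0.10)


def test_mak2_is_deterministic(noiseless_config):
    curve, _ = generate_curve(noiseless_config, 2)
    a, b = fit_mak2(curve), fit_mak2(curve)
    assert a.params == b.params and a.ssr == b.ssr and a.n_iterations == b.n_iterations


def test_mak2_ssr_hessian_nonsingular(noiseless_config):
    """The three parameters shape the curve in independent ways: the SSR
    Hessian at the optimum is numerically non-singular."""
    curve, _ = generate_curve(noiseless_config, 3)
    est = MAK2Regressor().fit_curve(curve)
    x0 = np.array([math.log10(est.d0_), math.log10(est.k_), est.fb_])
    mask = curve.cycles <= est.cutoff_cycle_
    yobs = curve.fluorescence[mask]

    def ssr(x):
        traj = simulate_trajectory(MAK2Params(10.0 ** x[0], 10.0 ** x[1], x[2]),
                                   int(curve.cycles[mask][-1]))
        r = traj.f[curve.cycles[mask] - 1] - yobs
        return float(r @ r)

    h = 1e-4
    hess = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            ei, ej = np.eye(3)[i] * h, np.eye(3)[j] * h
            hess[i, j] = (
                ssr(x0 + ei + ej) - ssr(x0 + ei - ej) - ssr(x0 - ei + ej) + ssr(x0 - ei - ej)
            ) / (4 * h * h)
    eigvals = np.linalg.eigvalsh(hess)
    assert np.all(eigvals > 0)
    assert eigvals[-1] / eigvals[0] < 1e10


def test_mak2_sklearn_interface(noiseless_config):
    from sklearn.base import clone

    curve, truth = generate_curve(noiseless_config, 2)
    est = MAK2Regressor()
    est2 = clone(est)  # get_params/set_params round trip
    est2.fit(curve.cycles.reshape(-1, 1), curve.fluorescence)
    assert abs(math.log10(est2.d0_ / truth["d0"])) < 0.05
    pred = est2.predict(curve.cycles[: est2.cutoff_cycle_].reshape(-1, 1))
    assert np.allclose(pred, curve.fluorescence[: est2.cutoff_cycle_], atol=0.02)


# ---------------------------------------------------------------------------
# Cq


def test_cq_fractional_interpolation():
    f = np.concatenate([np.zeros(13), [8.0, 16.0], np.full(5, 20.0)])
    res = compute_cq(make_curve(f), threshold=10.0, baseline=0.0)
    assert res.cq == pytest.approx(14.25)


def test_cq_exact_crossing_is_integer_cycle():
    f = np.concatenate([np.zeros(19), [10.0], np.full(5, 20.0)])
    res = compute_cq(make_curve(f), threshold=10.0, baseline=0.0)
    assert res.cq == pytest.approx(20.0)


def test_cq_no_crossing_raises():
    with pytest.raises(NoCrossingError):
        compute_cq(make_curve([0.0, 0.1, 0.2, 0.1, 0.0]), threshold=10.0, baseline=0.0)


def test_cq_crossing_at_first_cycle_is_flagged():
    f = np.array([5.0, 6.0, 7.0, 8.0])
    res = compute_cq(make_curve(f), threshold=1.0, baseline=0.0)
    assert res.cq == 1.0 and res.at_first_cycle


def test_cq_decade_spacing_on_doubling_curves(doubling_config):
    """Ten-fold dilution steps of ideal doubling curves are log2(10) cycles
    apart, and Cq falls strictly as template rises."""
    from qpcrfit.simulate import generate_dilution_series

    synth = generate_dilution_series(doubling_config)
    threshold = 0.1
    cqs = [
        compute_cq(c, threshold=threshold, baseline_cycles=5).cq
        for c in synth.series.curves
    ]
    spacing = -np.diff(cqs)
    assert np.all(np.diff(cqs) < 0)  # strictly monotone in D0
    assert np.all(np.abs(spacing - math.log2(10.0)) < 0.2)


# ---------------------------------------------------------------------------
# Exponential


def test_exponential_round_trip():
    n = np.arange(1, 31)
    curve = make_curve(0.5 + 1e-6 * np.power(1.9, n))
    res = fit_exponential(curve)
    assert res.params["fb"] == pytest.approx(0.5, rel=1e-6)
    assert res.params["e"] == pytest.approx(0.9, rel=1e-6)
    assert res.estimate_d0 == pytest.approx(1e-6, rel=1e-6)
    assert res.cycles_used[0] == 1  # window starts at cycle 1


def test_exponential_exact_doubling():
    curve = make_curve(np.power(2.0, np.arange(1, 9)))
    res = fit_exponential(curve)
    assert res.params["e"] == pytest.approx(1.0, abs=1e-9)
    assert res.estimate_d0 == pytest.approx(1.0, rel=1e-9)


def test_exponential_fails_on_constant_curve():
    with pytest.raises(FitFailureError):
        fit_exponential(make_curve(np.full(20, 3.0)))


# ---------------------------------------------------------------------------
# Log-logistic


TRUTH5 = dict(fb=0.5, fmax=5.0, b=-8.0, e=22.0, f=1.7)


def _ll_curve(truth, n_cycles=40):
    n = np.arange(1, n_cycles + 1)
    return make_curve(_ll_model(n.astype(float), **truth))


def test_loglogistic5_round_trip():
    res = fit_loglogistic(_ll_curve(TRUTH5), n_params=5)
    for name, value in TRUTH5.items():
        assert res.params[name] == pytest.approx(value, rel=1e-6)
    assert res.converged and not res.diagnostics["ill_conditioned"]


def test_loglogistic4_round_trip_and_nesting():
    truth4 = dict(TRUTH5, f=1.0)
    curve = _ll_curve(truth4)
    r4 = fit_loglogistic(curve, n_params=4)
    r5 = fit_loglogistic(curve, n_params=5)
    for name, value in truth4.items():
        assert r4.params[name] == pytest.approx(value, rel=1e-6)
    assert r5.params["f"] == pytest.approx(1.0, abs=1e-6)
    assert abs(r5.ssr - r4.ssr) < 1e-12


def test_loglogistic_flags_plateauless_curve():
    """With noise, a curve cut before its plateau leaves Fmax unconstrained:
    the fit must not pretend to know the asymptote."""
    rng = np.random.default_rng(3)
    f = _ll_model(np.arange(1, 41).astype(float), **TRUTH5) + rng.normal(0, 0.02, 40)
    full = fit_loglogistic(make_curve(f), n_params=5)
    assert not full.diagnostics["ill_conditioned"]
    try:
        cut = fit_loglogistic(make_curve(f[:20]), n_params=5)
        assert (not cut.converged) or cut.diagnostics["ill_conditioned"]
    except FitFailureError:
        pass


def test_two_stage_f0_recovers_initial_fluorescence():
    """Exponential data with saturation, quantified via the sigmoid fit and
    the second-stage exponential fit: F0 within two-fold of truth."""
    n = np.arange(1, 41).astype(float)
    sig = np.minimum(1e-6 * np.power(1.9, n), 5.0)
    theta, span = 0.3, 0.7
    u = np.maximum(sig - theta, 0.0) / span
    sat = np.where(sig <= theta, sig, theta + span * np.tanh(u + u**3 / 3))
    res = fit_loglogistic(make_curve(0.3 + sat), n_params=5)
    assert res.estimate_d0 is not None
    assert 0.5e-6 <= res.estimate_d0 <= 2e-6


def test_two_stage_f0_ordered_across_dilutions(noiseless_config):
    from dataclasses import replace

    from qpcrfit.simulate import generate_dilution_series

    cfg = replace(noiseless_config, replicates=1)
    synth = generate_dilution_series(cfg)
    f0s = [fit_loglogistic(c, n_params=5).estimate_d0 for c in synth.series.curves]
    assert all(a < b for a, b in zip(f0s, f0s[1:]))  # ordered with template
    span = f0s[-1] / f0s[0]
    assert 1e3 < span < 1e7  # roughly ten-fold per level over 5 steps
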