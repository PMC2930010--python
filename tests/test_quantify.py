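"""Dilution-series calibration, method comparison, and the k diagnostic."""

import numpy as np
import pytest

from qpcrfit import (
    DilutionCalibrator,
    DilutionSeries,
    InsufficientDataError,
    calibrate_series,
    k_dependence_diagnostic,
    run_method_comparison,
)
from qpcrfit.simulate import (
    GeneratorConfig,
    generate_dilution_series,
    generate_flat_curve,
)

from conftest import make_curve


def test_calibrator_perfect_proportionality():
    """Estimates exactly proportional to known amounts give slope 1, R^2 = 1,
    and back-prediction reproduces the knowns exactly."""
    known = np.array([1e2, 1e3, 1e4, 1e5])
    est = 3.7 * known
    cal = DilutionCalibrator().fit(np.log10(known), np.log10(est))
    assert cal.slope_ == pytest.approx(1.0)
    assert cal.r_squared_ == pytest.approx(1.0)
    back = 10.0 ** cal.inverse_predict(np.log10(est))
    assert np.allclose(back, known, rtol=1e-12)


def test_back_prediction_consistency():
    """Re-regressing the trend's own back-predictions gives the identity."""
    rng = np.random.default_rng(5)
    x = np.log10([1e1, 1e2, 1e3, 1e4, 1e5, 1e6])
    y = 0.93 * x - 0.4 + rng.normal(0, 0.05, x.size)
    cal = DilutionCalibrator().fit(x, y)
    back = cal.inverse_predict(y)
    recal = DilutionCalibrator().fit(back, y)
    # mapping back-predictions through the trend reproduces y exactly
    assert np.allclose(cal.predict(back), y, atol=1e-12)
    assert recal.slope_ == pytest.approx(cal.slope_, rel=1e-12)


def test_calibration_end_to_end_noiseless(noiseless_series):
    cal = calibrate_series(noiseless_series.series, "mak2")
    assert 0.95 <= cal.slope <= 1.05
    assert cal.r_squared > 0.999
    assert cal.n_used == len(noiseless_series.series.curves)


def test_degenerate_well_is_excluded_not_fatal():
    cfg = GeneratorConfig(replicates=1, seed=3)
    synth = generate_dilution_series(cfg)
    flat = generate_flat_curve(cfg)
    flat = make_curve(flat.fluorescence, well_id="NTC", known_copies=1.0)
    series = DilutionSeries(curves=synth.series.curves + [flat])
    cal = calibrate_series(series, "mak2")
    assert "NTC" in cal.excluded
    assert cal.n_used == len(synth.series.curves)


def test_too_few_levels_raises():
    cfg = GeneratorConfig(d0_levels=(1e-6, 1e-5), noise_sd=0.0, replicates=1)
    synth = generate_dilution_series(cfg)
    # drop one level -> only one usable concentration
    series = DilutionSeries(curves=synth.series.curves[:1])
    with pytest.raises(InsufficientDataError):
        calibrate_series(series, "mak2")


def test_cq_slope_near_ideal(doubling_config):
    from qpcrfit.simulate import generate_dilution_series as gen

    synth = gen(doubling_config)
    cal = calibrate_series(synth.series, "cq", baseline_cycles=5)
    assert cal.slope == pytest.approx(-np.log2(10.0), abs=0.2)
    assert cal.r_squared > 0.999


def test_k_diagnostic_constant_k(noiseless_config):
    """A series generated with a single k shows no trend of fitted k with
    template amount."""
    from dataclasses import replace

    synth = generate_dilution_series(replace(noiseless_config, replicates=1))
    diag = k_dependence_diagnostic(synth.series)
    assert len(diag.per_curve) == 6
    assert abs(diag.slope) <= 2.5 * diag.stderr
    # over the 5-decade span the implied k change is under 10% of k
    assert abs(diag.slope) * 5.0 < 0.1 * noiseless_config.k


def test_k_diagnostic_recovers_injected_drift():
    cfg = GeneratorConfig(k_drift=-0.05, noise_sd=0.0, replicates=1)
    synth = generate_dilution_series(cfg)
    diag = k_dependence_diagnostic(synth.series)
    assert diag.slope == pytest.approx(-0.05, rel=0.20)


def test_k_diagnostic_single_level_reports_per_curve_only():
    cfg = GeneratorConfig(noise_sd=0.0, replicates=2)
    synth = generate_dilution_series(cfg)
    one_level = DilutionSeries(curves=[c for c in synth.series.curves if c.well_id.startswith("L3")])
    diag = k_dependence_diagnostic(one_level)
    assert len(diag.per_curve) == 2
    assert diag.slope is None


def test_method_comparison_structure(noiseless_series):
    report = run_method_comparison(noiseless_series.series, methods=("mak2", "cq"))
    assert set(report.calibrations) == {"mak2", "cq"}
    assert report.calibrations["mak2"].r_squared >= 0.99
    assert report.calibrations["cq"].r_squared >= 0.99
    table = report.table
    assert set(table["method"]) == {"mak2", "cq"}
    assert (table["status"] == "ok").all()


def test_method_comparison_empty_methods(noiseless_series):
    report = run_method_comparison(noiseless_series.series, methods=())
    assert report.calibrations == {} and report.table.empty


def test_method_comparison_failed_method_isolated():
    """A method that fails on every well is reported as failed while the
    others proceed: plateau-less curves sink the log-logistic fit only."""
    cfg = GeneratorConfig(noise_sd=0.01, seed=9, replicates=1, n_cycles=40)
    synth = generate_dilution_series(cfg)
    truncated = [
        make_curve(
            c.fluorescence[:22], well_id=c.well_id, known_copies=c.known_copies
        )
        for c in synth.series.curves
    ]
    report = run_method_comparison(
        DilutionSeries(curves=truncated), methods=("cq", "loglogistic4")
    )
    assert "cq" in report.calibrations
    ll_failed = "loglogistic4" in report.failures or (
        "loglogistic4" in report.calibrations
        and report.calibrations["loglogistic4"].n_used < len(truncated)
    )
    assert ll_failed
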