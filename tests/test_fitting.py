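"""Discrepancy, parameter fitting and the single-parameter scan."""

import numpy as np
import pytest

from axotrace.cohort import generate_recorded_excitability
from axotrace.fitting import (DiscrepancyWeights, ExcitabilityModel,
                              add_second_parameter, discrepancy,
                              fit_parameters, simulate_on_lattices,
                              single_parameter_scan)
from tests.conftest import SMALL_OPTS


@pytest.fixture(scope="module")
def clean_curves(default_params):
    return generate_recorded_excitability(default_params, noise_sd=0.0,
                                          seed=0, tracker_opts=SMALL_OPTS)


def _offset_rc(curves, delta):
    rc = curves.rc.copy()
    rc[:, 1] = rc[:, 1] + delta
    from axotrace.protocols import ExcitabilityCurves

    return ExcitabilityCurves(sd=curves.sd.copy(),
                              te={k: v.copy() for k, v in curves.te.items()},
                              iv=curves.iv.copy(), rc=rc)


def test_discrepancy_is_pseudometric(clean_curves):
    w = DiscrepancyWeights()
    assert discrepancy(clean_curves, clean_curves, w) == 0.0
    other = _offset_rc(clean_curves, 1.0)
    d_ab = discrepancy(clean_curves, other, w)
    d_ba = discrepancy(other, clean_curves, w)
    assert d_ab == d_ba > 0.0


def test_unit_rc_offset_gives_discrepancy_three(clean_curves):
    """3 (rc weight) * mean of squared 1-unit residuals = 3.0 exactly."""
    other = _offset_rc(clean_curves, 1.0)
    assert discrepancy(clean_curves, other) == pytest.approx(3.0, abs=1e-12)


def test_weights_scale_their_paradigm_exactly(clean_curves):
    other = _offset_rc(clean_curves, 1.0)
    d1 = discrepancy(clean_curves, other, DiscrepancyWeights())
    d2 = discrepancy(clean_curves, other, DiscrepancyWeights(w_rc=6.0))
    assert d2 == pytest.approx(2.0 * d1, rel=1e-12)


def test_mismatched_lattices_rejected(clean_curves):
    from axotrace.protocols import ExcitabilityCurves

    shifted = ExcitabilityCurves(
        sd=clean_curves.sd, te=clean_curves.te, iv=clean_curves.iv,
        rc=clean_curves.rc[:-1])
    with pytest.raises(ValueError, match="lattice"):
        discrepancy(clean_curves, shifted)


def test_empty_paradigm_with_nonzero_weight_rejected(clean_curves):
    from axotrace.protocols import ExcitabilityCurves

    empty_sd = ExcitabilityCurves(sd=np.empty((0, 2)), te=clean_curves.te,
                                  iv=clean_curves.iv, rc=clean_curves.rc)
    with pytest.raises(ValueError, match="empty"):
        discrepancy(empty_sd, empty_sd)
    # zero weight on the empty paradigm is fine
    assert discrepancy(empty_sd, empty_sd, DiscrepancyWeights(w_sd=0.0)) == 0.0


def test_self_fit_changes_nothing(default_params, clean_curves):
    fr = fit_parameters(default_params, clean_curves, ["I_pump"],
                        maxfev=20, tracker_opts=SMALL_OPTS)
    base, fitted = fr.changed_parameters["I_pump"]
    assert fr.discrepancy_before == pytest.approx(0.0, abs=1e-9)
    assert abs(fitted - base) < 1.0
    assert fr.converged


def test_pump_change_recovered_from_noise_free_curves(default_params):
    truth = default_params.with_changes(I_pump=default_params.I_pump - 15.0)
    rec = generate_recorded_excitability(truth, noise_sd=0.0, seed=0,
                                         tracker_opts=SMALL_OPTS)
    fr = fit_parameters(default_params, rec, ["I_pump"], maxfev=30,
                        tracker_opts=SMALL_OPTS)
    base, fitted = fr.changed_parameters["I_pump"]
    assert fitted - base == pytest.approx(-15.0, abs=2.0)
    assert fr.pct_reduction > 80.0


def test_nested_fit_never_worse(default_params):
    truth = default_params.with_changes(I_pump=default_params.I_pump - 15.0)
    rec = generate_recorded_excitability(truth, noise_sd=0.5, seed=4,
                                         tracker_opts=SMALL_OPTS)
    single = fit_parameters(default_params, rec, ["I_pump"], maxfev=25,
                            tracker_opts=SMALL_OPTS)
    _, best_val = single.changed_parameters["I_pump"]
    double = fit_parameters(default_params, rec, ["I_pump", "G_H"],
                            maxfev=40, tracker_opts=SMALL_OPTS,
                            start_values={"I_pump": best_val})
    assert double.discrepancy_after <= single.discrepancy_after + 1e-12


def test_fits_reproducible_for_fixed_seed(default_params):
    truth = default_params.with_changes(G_H=default_params.G_H * 1.5)
    rec = generate_recorded_excitability(truth, noise_sd=1.0, seed=2,
                                         tracker_opts=SMALL_OPTS)
    a = fit_parameters(default_params, rec, ["G_H"], seed=5, maxfev=20,
                       tracker_opts=SMALL_OPTS)
    b = fit_parameters(default_params, rec, ["G_H"], seed=5, maxfev=20,
                       tracker_opts=SMALL_OPTS)
    assert a.changed_parameters == b.changed_parameters
    assert a.discrepancy_after == b.discrepancy_after


def test_scan_ranks_perturbed_parameter_first(default_params):
    truth = default_params.with_changes(I_pump=default_params.I_pump - 15.0)
    rec = generate_recorded_excitability(truth, noise_sd=0.0, seed=0,
                                         tracker_opts=SMALL_OPTS)
    scan = single_parameter_scan(
        default_params, rec, candidates=("I_pump", "G_H", "G_NaT", "G_Lk_i"),
        maxfev=22, tracker_opts=SMALL_OPTS)
    assert scan.best == "I_pump"
    assert scan.ranking[0][2] > 80.0
    assert scan.baseline.discrepancy_before > 0.0
    # incremental second parameters explain little once the pump is fitted
    extras = add_second_parameter(scan, default_params, rec,
                                  candidates=("I_pump", "G_H", "G_NaT"),
                                  maxfev=30, tracker_opts=SMALL_OPTS)
    assert all(gain < 10.0 for _, gain in extras)


def test_model_results_interface(default_params):
    truth = default_params.with_changes(I_pump=default_params.I_pump - 15.0)
    rec = generate_recorded_excitability(truth, noise_sd=0.0, seed=0,
                                         tracker_opts=SMALL_OPTS)
    model = ExcitabilityModel(rec, default_params)
    res = model.fit(["I_pump"], maxfev=25, tracker_opts=SMALL_OPTS)
    txt = res.summary()
    assert "I_pump" in txt and "reduction" in txt
    assert res.pct_reduction > 50.0
    sim = simulate_on_lattices(res.params, rec, SMALL_OPTS)
    assert discrepancy(sim, rec) == pytest.approx(res.fit.discrepancy_after,
                                                  rel=1e-9)
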