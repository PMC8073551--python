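"""Two-condition differential rhythmicity and multiple-testing adjustment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhythmfit import (
    GeneTruth,
    SyntheticDesign,
    ValidationError,
    adjust_pvalues,
    compare_series,
    fit_cosinor,
    fit_differential,
    simulate_expression,
    wrap_hours,
)

TAU = 24.0


def _slices(truth, conditions=("K", "BJ17"), seed=0):
    design = SyntheticDesign(genes=("g",), conditions=conditions, seed=seed)
    expr = simulate_expression(design, {"g": truth})
    out = []
    for c in conditions:
        s = expr[expr.condition == c]
        out.extend([s["time_h"].to_numpy(), s["value"].to_numpy()])
    return out


def test_identity_perturbation_has_no_effect():
    t, y, *_ = _slices(GeneTruth(mesor=5, amplitude=2, acrophase=-1.0))
    fit = fit_differential(t, y, t, y)
    assert fit.alpha2 == pytest.approx(0.0, abs=1e-10)
    assert fit.beta2 == pytest.approx(0.0, abs=1e-10)
    assert fit.amplitude_change == pytest.approx(0.0, abs=1e-10)
    assert fit.phase_shift_hours == pytest.approx(0.0, abs=1e-9)
    # noiseless identical slices: degenerate convention, everything null
    assert fit.p_differential_rhythmicity == 1.0
    assert fit.p_amplitude == 1.0 and fit.p_phase == 1.0 and fit.degenerate


def test_planted_phase_advance_recovered_exactly():
    truth = GeneTruth(mesor=5, amplitude=2, acrophase=-math.pi / 2,
                      phase_shift={"BJ17": 4.0})
    t1, y1, t2, y2 = _slices(truth)
    fit = fit_differential(t1, y1, t2, y2)
    assert fit.phase_shift_hours == pytest.approx(4.0, abs=1e-9)
    assert fit.amplitude_fold == pytest.approx(1.0, abs=1e-10)
    assert fit.p_differential_rhythmicity == 0.0 and fit.degenerate


def test_planted_amplitude_doubling_recovered_exactly():
    truth = GeneTruth(mesor=5, amplitude=2, acrophase=-math.pi / 2,
                      amplitude_scale={"BJ17": 2.0})
    t1, y1, t2, y2 = _slices(truth)
    fit = fit_differential(t1, y1, t2, y2)
    assert fit.amplitude_fold == pytest.approx(2.0, abs=1e-10)
    assert fit.phase_shift_hours == pytest.approx(0.0, abs=1e-9)


def test_phase_wraps_into_half_period_window():
    """A planted advance of tau - 4 h reads as a 4 h delay."""
    truth = GeneTruth(mesor=5, amplitude=2, acrophase=-math.pi / 2,
                      phase_shift={"BJ17": TAU - 4.0})
    t1, y1, t2, y2 = _slices(truth)
    fit = fit_differential(t1, y1, t2, y2)
    assert fit.phase_shift_hours == pytest.approx(-4.0, abs=1e-9)


def test_label_swap_antisymmetry():
    truth = GeneTruth(mesor=5, amplitude=2, acrophase=-1.2,
                      amplitude_scale={"BJ17": 1.6}, phase_shift={"BJ17": 3.0},
                      noise_sd=0.3)
    t1, y1, t2, y2 = _slices(truth, seed=5)
    ab = fit_differential(t1, y1, t2, y2)
    ba = fit_differential(t2, y2, t1, y1)
    assert ba.amplitude_change == pytest.approx(-ab.amplitude_change, abs=1e-9)
    assert ba.phase_shift_hours == pytest.approx(-ab.phase_shift_hours, abs=1e-9)
    assert ba.p_differential_rhythmicity == pytest.approx(
        ab.p_differential_rhythmicity, abs=1e-12)


def test_separate_mesor_reproduces_independent_cosinor_fits():
    """With its own intercept per condition the stacked model factorizes into
    the two single-condition regressions."""
    rng = np.random.default_rng(8)
    t = np.repeat(np.arange(2.0, 26.0, 2.0), 2)
    y1 = 4 + 2 * np.cos(2 * np.pi * t / TAU - 1) + rng.normal(0, 0.4, t.size)
    y2 = 7 + 1.2 * np.cos(2 * np.pi * t / TAU - 2.5) + rng.normal(0, 0.4, t.size)
    joint = fit_differential(t, y1, t, y2, shared_mesor=False)
    f1 = fit_cosinor(t, y1, TAU)
    f2 = fit_cosinor(t, y2, TAU)
    assert joint.alpha1 == pytest.approx(f1.alpha, abs=1e-9)
    assert joint.beta1 == pytest.approx(f1.beta, abs=1e-9)
    assert joint.mesor == pytest.approx(f1.mesor, abs=1e-9)
    assert joint.alpha1 + joint.alpha2 == pytest.approx(f2.alpha, abs=1e-9)
    assert joint.beta1 + joint.beta2 == pytest.approx(f2.beta, abs=1e-9)
    assert joint.mesor_perturbed == pytest.approx(f2.mesor, abs=1e-9)
    assert joint.amplitude_control == pytest.approx(f1.amplitude, abs=1e-9)
    assert joint.amplitude_perturbed == pytest.approx(f2.amplitude, abs=1e-9)


def test_joint_test_type_one_error_under_null():
    rng = np.random.default_rng(99)
    t = np.repeat(np.arange(2.0, 26.0, 2.0), 2)
    clean = 4 + 2 * np.cos(2 * np.pi * t / TAU - 1)
    reps = 2000
    rejections = sum(
        fit_differential(t, clean + rng.normal(0, 1, t.size),
                         t, clean + rng.normal(0, 1, t.size)
                         ).p_differential_rhythmicity < 0.05
        for _ in range(reps))
    assert rejections / reps == pytest.approx(0.05, abs=0.015)


def test_power_to_detect_planted_phase_advance():
    """A 4 h advance at amplitude 2, sigma 0.2, n=24 per condition is
    detected by the phase test nearly always."""
    truth = GeneTruth(mesor=5, amplitude=2, acrophase=-math.pi / 2,
                      phase_shift={"BJ17": 4.0}, noise_sd=0.2)
    hits = 0
    reps = 200
    for seed in range(reps):
        t1, y1, t2, y2 = _slices(truth, seed=seed)
        if fit_differential(t1, y1, t2, y2).p_phase < 0.05:
            hits += 1
    assert hits / reps > 0.9


def test_bh_adjustment_matches_hand_stepup():
    assert adjust_pvalues([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])
    assert adjust_pvalues([1.0]) == [1.0]


def test_sidak_adjustment_closed_form():
    assert adjust_pvalues([0.05, 0.2, 0.9], "sidak") == pytest.approx(
        [1 - 0.95 ** 3, 1 - 0.8 ** 3, 1 - 0.1 ** 3])
    assert adjust_pvalues([1.0], "sidak") == [1.0]


def test_adjustment_rejects_invalid_pvalues():
    with pytest.raises(ValidationError):
        adjust_pvalues([0.5, 1.5])
    with pytest.raises(ValidationError):
        adjust_pvalues([0.5], method="bonferroni-ish")


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=100, derandomize=True)
def test_adjusted_pvalues_dominate_raw(pvals):
    bh = adjust_pvalues(pvals)
    sidak = adjust_pvalues(pvals, "sidak")
    for raw, q, s in zip(pvals, bh, sidak):
        assert q >= raw - 1e-12 and q <= 1.0
        assert s >= raw - 1e-12 and s <= 1.0
    # BH preserves the ordering of raw p-values
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(np.asarray(bh)[order]) >= -1e-12)


@given(delta=st.floats(-100, 100))
@settings(max_examples=100, derandomize=True)
def test_wrap_hours_window(delta):
    h = wrap_hours(delta, TAU)
    assert -TAU / 2 < h <= TAU / 2
    assert (h - delta) % TAU == pytest.approx(0.0, abs=1e-9) or \
           (h - delta) % TAU == pytest.approx(TAU, abs=1e-9)


def test_compare_series_counts_and_families(multigene_series):
    diff = compare_series(multigene_series, control="K",
                          perturbed=["BJ17", "BJ23"])
    assert len(diff) == 14  # 7 genes x 2 pairs
    assert (diff["p_differential_adjusted"]
            >= diff["p_differential_rhythmicity"] - 1e-12).all()
    # BJ23 carries a planted 2 h advance for every gene
    bj23 = diff[diff["perturbed"] == "BJ23"]
    assert bj23["phase_shift_hours"].median() == pytest.approx(2.0, abs=0.5)


def test_compare_series_rejects_unknown_condition(multigene_series):
    with pytest.raises(ValidationError):
        compare_series(multigene_series, control="K", perturbed="BJ99")
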