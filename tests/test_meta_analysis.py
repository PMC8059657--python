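"""Factorial-experiment ingestion, effect derivation, envelope classification."""

import math

import numpy as np
import pandas as pd
import pytest

from multistress.meta_analysis import (
    ExperimentValidationError,
    FactorialExperiment,
    bias_precision,
    classify_all,
    derive_effects,
    filter_experiments,
    load_experiments,
    predict_envelope,
)


def make_exp(control, a, b, ab, kind="mortality", eid="e1"):
    return FactorialExperiment(eid, kind, control, a, b, ab)


# --- ingestion -------------------------------------------------------------

def test_load_well_formed_csv(tmp_path):
    p = tmp_path / "exp.csv"
    p.write_text(
        "experiment_id,endpoint_kind,control,stressor_a,stressor_b,combined\n"
        "e1,mortality,0.10,0.40,0.21,0.65\n"
        "e2,survival,0.90,0.60,0.79,0.35\n"
        "e3,mortality,0.0,0.2,0.2,0.4\n"
    )
    exps = load_experiments(p)
    assert len(exps) == 3
    # a mortality-endpoint row passes through without the 1-x flip
    assert exps[0].mortality("a") == pytest.approx(0.40)
    # survival endpoint is flipped
    assert exps[1].mortality("a") == pytest.approx(0.40)


def test_load_reports_bad_rows_with_numbers(tmp_path):
    p = tmp_path / "exp.csv"
    p.write_text(
        "experiment_id,endpoint_kind,control,stressor_a,stressor_b,combined\n"
        "e1,survival,0.9,1.02,0.8,0.5\n"
        "e2,mortality,0.1,0.2,0.3,0.4\n"
        "e3,growth,0.1,0.2,0.3,0.4\n"
    )
    with pytest.raises(ExperimentValidationError) as exc:
        load_experiments(p)
    msg = str(exc.value)
    assert "row 2" in msg and "row 4" in msg and "row 3" not in msg


def test_load_missing_column(tmp_path):
    p = tmp_path / "exp.csv"
    p.write_text("experiment_id,endpoint_kind,control,stressor_a,stressor_b\n")
    with pytest.raises(ExperimentValidationError, match="combined"):
        load_experiments(p)


# --- effects and filtering -------------------------------------------------

def test_derive_effects_subtraction_and_scope():
    eff = derive_effects(make_exp(0.10, 0.40, 0.21, 0.65))
    assert eff.effect_a == pytest.approx(0.30)
    assert eff.effect_b == pytest.approx(0.11)
    assert eff.observed_joint == pytest.approx(0.55)
    assert eff.scope == pytest.approx(0.90)


def test_derive_effects_survival_conversion():
    eff = derive_effects(make_exp(0.90, 0.60, 0.80, 0.50, kind="survival"))
    assert eff.effect_a == pytest.approx(0.30)


def test_endpoint_symmetry_through_whole_pipeline():
    """The same experiment fed as survival vs pre-converted mortality gives
    identical downstream numbers."""
    surv = make_exp(0.90, 0.60, 0.79, 0.35, kind="survival")
    mort = make_exp(0.10, 0.40, 0.21, 0.65, kind="mortality")
    ca, cb = predict_envelope(derive_effects(surv)), predict_envelope(derive_effects(mort))
    assert ca.predictions == cb.predictions
    assert ca.ca_values == cb.ca_values
    assert ca.category == cb.category


def test_filter_splits_on_negative_individual_effects():
    effs = [
        derive_effects(make_exp(0.1, 0.4, 0.2, 0.5, eid="ok")),
        derive_effects(make_exp(0.1, 0.05, 0.2, 0.5, eid="protective_a")),
        derive_effects(make_exp(0.1, 0.4, 0.05, 0.5, eid="protective_b")),
    ]
    kept, excluded = filter_experiments(effs)
    assert [k.experiment_id for k in kept] == ["ok"]
    reasons = {e.experiment_id: r for e, r in excluded}
    assert "stressor A increased survival" in reasons["protective_a"]
    assert "stressor B increased survival" in reasons["protective_b"]
    assert len(kept) + len(excluded) == len(effs)


def test_filter_keeps_negative_joint_effects():
    # combined mortality below control is retained (the filter names only
    # the individual stressors) and classifies below the envelope
    eff = derive_effects(make_exp(0.2, 0.3, 0.3, 0.05))
    kept, excluded = filter_experiments([eff])
    assert kept and not excluded
    c = predict_envelope(eff)
    assert c.category == "below"


# --- envelope --------------------------------------------------------------

def test_envelope_spans_fig_example():
    eff = derive_effects(make_exp(0.0, 0.30, 0.11, 0.55))
    c = predict_envelope(eff)
    assert c.envelope_low <= 0.30 + 1e-12
    assert c.envelope_high >= 0.78 - 0.01
    assert c.predictions["dominance"] == pytest.approx(0.30)
    assert c.category == "within"


def test_zero_effects_collapse_envelope():
    eff = derive_effects(make_exp(0.2, 0.2, 0.2, 0.2))
    c = predict_envelope(eff)
    assert c.envelope_low == pytest.approx(0.0, abs=1e-9)
    assert c.envelope_high == pytest.approx(0.0, abs=1e-9)
    assert c.category == "within"


def test_linear_linear_ca_combination_equals_simple_addition():
    eff = derive_effects(make_exp(0.0, 0.2, 0.2, 0.4))
    c = predict_envelope(eff, shapes=["linear"])
    assert c.ca_values == pytest.approx((0.4,), abs=1e-6)
    assert c.ca_summary == pytest.approx(c.predictions["simple_addition"], abs=1e-6)


def test_envelope_contains_dominance_member():
    eff = derive_effects(make_exp(0.05, 0.5, 0.3, 0.6))
    c = predict_envelope(eff)
    assert c.envelope_low <= c.predictions["dominance"] <= c.envelope_high


def test_closed_envelope_boundary_counts_as_within():
    eff = derive_effects(make_exp(0.0, 0.3, 0.1, 0.3))
    c = predict_envelope(eff)
    # dominance == 0.3 is the envelope minimum here; observed equals it
    assert c.envelope_low == pytest.approx(0.3, abs=1e-9)
    assert c.category == "within"


def test_scope_zero_is_degenerate():
    eff = derive_effects(make_exp(1.0, 1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="scope"):
        predict_envelope(eff)


def test_effect_above_scope_clips_intensity():
    # rounding in source tables can push an effect marginally above scope;
    # the implied intensity is clipped to 1 instead of raising
    from multistress.meta_analysis import ExperimentEffects

    eff = ExperimentEffects("rounded", effect_a=0.905, effect_b=0.3,
                            observed_joint=0.9, scope=0.90)
    c = predict_envelope(eff)  # must not raise
    assert max(c.ca_values) <= 0.90 + 1e-9


# --- classification summary and accuracy -----------------------------------

def test_classify_all_breakdown_and_sa_window():
    effs = [
        derive_effects(make_exp(0.0, 0.3, 0.1, 0.42, eid="near_sa")),  # within
        derive_effects(make_exp(0.0, 0.1, 0.1, 0.99, eid="syn")),      # above
        derive_effects(make_exp(0.0, 0.4, 0.4, 0.1, eid="ant")),       # below
    ]
    out = classify_all(effs)
    assert out["n"] == 3
    b = out["breakdown_pct"]
    assert b["within"] == pytest.approx(100 / 3)
    assert b["above"] == pytest.approx(100 / 3)
    assert b["below"] == pytest.approx(100 / 3)
    # only the first observation is within 5 points of its Simple Addition
    assert out["within_sa_window_pct"] == pytest.approx(100 / 3)


def test_single_experiment_above_envelope():
    out = classify_all([derive_effects(make_exp(0.0, 0.05, 0.05, 0.95))])
    assert out["breakdown_pct"]["above"] == 100.0


def test_classification_invariant_to_input_order():
    effs = [
        derive_effects(make_exp(0.05, 0.3, 0.2, 0.5, eid=f"e{i}"))
        for i in range(3)
    ] + [derive_effects(make_exp(0.0, 0.1, 0.1, 0.9, eid="x"))]
    a = classify_all(effs)["table"].sort_values("experiment_id").reset_index(drop=True)
    b = classify_all(effs[::-1])["table"].sort_values("experiment_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_bias_precision_arithmetic():
    effs = [
        derive_effects(make_exp(0.0, 0.0, 0.0, 0.10, eid="lo")),   # all predict 0
        derive_effects(make_exp(0.0, 0.0, 0.0, 0.0, eid="mid")),
    ]
    cls = classify_all(effs)["classifications"]
    table = bias_precision(cls).set_index("model")
    # differences are (0 - 0.10)*100 = -10 and 0 for every model
    assert table.loc["dominance", "bias_pct"] == pytest.approx(-5.0)
    assert table.loc["dominance", "precision_pct"] == pytest.approx(
        100 * np.std([-0.1, 0.0], ddof=1)
    )


def test_bias_precision_two_point_sd():
    # differences +10 and -10 points: bias 0, sample SD 14.14
    effs = [
        derive_effects(make_exp(0.0, 0.2, 0.0, 0.10, eid="a")),  # preds 0.2, obs 0.1
        derive_effects(make_exp(0.0, 0.2, 0.0, 0.30, eid="b")),  # preds 0.2, obs 0.3
    ]
    cls = classify_all(effs)["classifications"]
    table = bias_precision(cls).set_index("model")
    assert table.loc["dominance", "bias_pct"] == pytest.approx(0.0, abs=1e-9)
    assert table.loc["dominance", "precision_pct"] == pytest.approx(
        math.sqrt(2) * 10, abs=1e-6
    )


def test_bias_precision_needs_two_experiments():
    cls = classify_all([derive_effects(make_exp(0.0, 0.1, 0.1, 0.2))])[
        "classifications"
    ]
    with pytest.raises(ValueError):
        bias_precision(cls)


def test_identical_predictions_and_observations_zero_bias():
    effs = [
        derive_effects(make_exp(0.0, 0.3, 0.0, 0.30, eid="a")),
        derive_effects(make_exp(0.0, 0.5, 0.0, 0.50, eid="b")),
    ]
    cls = classify_all(effs)["classifications"]
    table = bias_precision(cls).set_index("model")
    # with one absent stressor every model predicts the single effect exactly
    for m in ("simple_addition", "multiplicative", "dominance"):
        assert table.loc[m, "bias_pct"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc[m, "precision_pct"] == pytest.approx(0.0, abs=1e-9)
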