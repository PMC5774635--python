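import numpy as np
import pytest

from popadjust import (
    ArmSummary,
    CovariateSpec,
    TargetPopulation,
    CovariateSummary,
    absolute_effects,
    anchored_comparison,
    bucher,
    check_assumptions,
    transport_effect,
    trial_relative_effect,
    unanchored_comparison,
)
from popadjust.comparison import SHARED_EM_WARNING, UNANCHORED_WARNING

A = lambda arm, ybar, se=0.1, n=100: ArmSummary(arm=arm, n=n, ybar=ybar, se_ybar=se)


# -- within-trial effects ---------------------------------------------

def test_identity_difference():
    eff = trial_relative_effect(A("B", 5.0), A("A", 2.0), "identity")
    assert eff.estimate == pytest.approx(3.0)
    assert eff.se == pytest.approx(np.sqrt(0.02))


def test_logit_log_odds_ratio():
    eff = trial_relative_effect(A("B", 0.5), A("A", 0.3), "logit")
    assert eff.estimate == pytest.approx(0.8472978603872036, abs=1e-10)


def test_log_equal_means_is_zero():
    eff = trial_relative_effect(A("B", 2.0), A("A", 2.0), "log")
    assert eff.estimate == 0.0


def test_continuity_correction_at_boundary(caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="popadjust"):
        eff = trial_relative_effect(A("B", 0.0, se=0.0, n=10), A("A", 0.3), "logit")
    assert "continuity correction" in caplog.text
    assert np.isfinite(eff.estimate)


# -- Bucher -----------------------------------------------------------

def test_bucher_estimate_and_variance_addition():
    d_ab = trial_relative_effect(A("B", 1.0, 0.1), A("A", 0.5, 0.0001), "identity")
    d_ac = trial_relative_effect(A("C", 1.3, 0.2), A("A", 0.5, 0.0001), "identity")
    res = bucher(d_ac, d_ab)
    assert res.estimate == pytest.approx(0.3)
    assert res.se == pytest.approx(np.sqrt(0.05), abs=1e-4)
    assert res.anchored
    assert res.population == "assumed-constant"


def test_bucher_zero_when_effects_equal():
    d = trial_relative_effect(A("B", 1.0), A("A", 0.5), "identity")
    d2 = trial_relative_effect(A("C", 1.0), A("A", 0.5), "identity")
    assert bucher(d2, d).estimate == pytest.approx(0.0)


def test_bucher_scale_mismatch():
    d_ab = trial_relative_effect(A("B", 0.4), A("A", 0.3), "logit")
    d_ac = trial_relative_effect(A("C", 0.4), A("A", 0.3), "log")
    with pytest.raises(ValueError, match="scale mismatch"):
        bucher(d_ac, d_ab)


# -- anchored / unanchored --------------------------------------------

def test_anchored_identity_arithmetic():
    res = anchored_comparison(
        A("A", 1.0), A("B", 3.0), A("A", 2.0), A("C", 5.0), "identity"
    )
    assert res.estimate == pytest.approx(1.0)
    assert res.anchored and res.population == "AC"


def test_anchored_logit_arithmetic():
    res = anchored_comparison(
        A("A", 0.3), A("B", 0.4), A("A", 0.3), A("C", 0.5), "logit"
    )
    # logit(0.5)-logit(0.3) = 0.84730; logit(0.4)-logit(0.3) = 0.44183
    assert res.estimate == pytest.approx(0.4054651081081643, abs=1e-10)


def test_anchored_null_case():
    res = anchored_comparison(
        A("A", 2.0), A("B", 4.0), A("A", 2.0), A("C", 4.0), "identity"
    )
    assert res.estimate == pytest.approx(0.0)


def test_unanchored_identity():
    res = unanchored_comparison(A("B", 3.0), A("C", 5.0), "identity")
    assert res.estimate == pytest.approx(2.0)
    assert not res.anchored
    assert UNANCHORED_WARNING in res.warnings


def test_unanchored_refused_when_anchored_available():
    with pytest.raises(ValueError, match="anchored"):
        unanchored_comparison(
            A("B", 3.0), A("C", 5.0), "identity", anchored_available=True
        )


def test_anchored_equals_unanchored_when_baselines_cancel():
    """Algebraic identity: if g(yhat_A) = g(ybar_A) the two estimators agree."""
    pred_a, pred_b = A("A", 2.0), A("B", 3.0)
    obs_a, obs_c = A("A", 2.0), A("C", 5.0)
    anch = anchored_comparison(pred_a, pred_b, obs_a, obs_c, "identity")
    unanch = unanchored_comparison(pred_b, obs_c, "identity")
    assert anch.estimate == pytest.approx(unanch.estimate, abs=1e-12)


# -- transport --------------------------------------------------------

def make_result():
    return anchored_comparison(
        A("A", 1.0), A("B", 3.0), A("A", 2.0), A("C", 5.0), "identity"
    )


def test_transport_relabels_under_shared_em():
    target = TargetPopulation(label="registry-P")
    res = transport_effect(make_result(), target, shared_em=True, treatment_set=("B", "C"))
    assert res.population == "registry-P"
    assert res.estimate == make_result().estimate
    assert res.shared_em_used
    assert SHARED_EM_WARNING in res.warnings


def test_transport_idempotent():
    target = TargetPopulation(label="P")
    once = transport_effect(make_result(), target, shared_em=True, treatment_set=("B", "C"))
    twice = transport_effect(once, target, shared_em=True, treatment_set=("B", "C"))
    assert twice == once


def test_transport_requires_shared_em():
    with pytest.raises(ValueError, match="shared"):
        transport_effect(make_result(), TargetPopulation(label="P"), shared_em=False)


def test_transport_respects_treatment_set():
    with pytest.raises(ValueError, match="not in the declared"):
        transport_effect(
            make_result(), TargetPopulation(label="P"), shared_em=True,
            treatment_set=("B",),
        )


# -- absolute effects -------------------------------------------------

def test_absolute_effects_logit():
    from popadjust import TrialEffect, get_scale

    target = TargetPopulation(
        label="P", baseline_A=ArmSummary("A", 100, 0.3, 0.02)
    )
    d_ab = TrialEffect(("B", "A"), "P", get_scale("logit"), 0.5, 0.1)
    out = absolute_effects(target, d_ab=d_ab, scale="logit")
    assert out["B"].ybar == pytest.approx(0.41403783590263243, abs=1e-8)


def test_absolute_effects_identity_and_null():
    from popadjust import TrialEffect, get_scale

    target = TargetPopulation(label="P", baseline_A=ArmSummary("A", 50, 2.0, 0.1))
    d_ac = TrialEffect(("C", "A"), "P", get_scale("identity"), 3.0, 0.2)
    d_ab = TrialEffect(("B", "A"), "P", get_scale("identity"), 0.0, 0.2)
    out = absolute_effects(target, d_ab=d_ab, d_ac=d_ac, scale="identity")
    assert out["C"].ybar == pytest.approx(5.0)
    assert out["B"].ybar == pytest.approx(2.0)


def test_absolute_effects_requires_baseline_and_matching_population():
    from popadjust import TrialEffect, get_scale

    with pytest.raises(ValueError, match="baseline"):
        absolute_effects(TargetPopulation(label="P"), scale="identity")
    target = TargetPopulation(label="P", baseline_A=ArmSummary("A", 50, 2.0, 0.1))
    d = TrialEffect(("B", "A"), "Q", get_scale("identity"), 1.0, 0.1)
    with pytest.raises(ValueError, match="population"):
        absolute_effects(target, d_ab=d, scale="identity")


# -- assumption checks ------------------------------------------------

SPEC = [
    CovariateSpec("em1", role="effect_modifier"),
    CovariateSpec("pg1", role="prognostic"),
    CovariateSpec("bt1", role="both"),
]


def test_anchored_weighting_overmatching_warning():
    warns = check_assumptions("maic", SPEC, True, ["em1", "bt1", "pg1"])
    assert any("over-matching" in w and "pg1" in w for w in warns)


def test_anchored_weighting_missing_em_warning():
    warns = check_assumptions("maic", SPEC, True, ["em1"])
    assert any("bt1" in w and "effect modifier" in w for w in warns)


def test_unanchored_missing_prognostic_warning():
    warns = check_assumptions("maic", SPEC, False, ["em1", "bt1"])
    assert any("pg1" in w for w in warns)


def test_compliant_anchored_stc_emits_only_mandatory_statements():
    warns = check_assumptions("stc", SPEC, True, ["em1", "bt1", "pg1"], "logit", "AC")
    assert warns == [
        "comparison carried out on the logit linear predictor scale",
        "target population: AC",
    ]
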