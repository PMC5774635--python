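"""Forming and transporting indirect comparisons.

Within-trial relative effects are differences of linked arm summaries,
``g(ybar_1) - g(ybar_0)``.  A standard (Bucher) indirect comparison
subtracts the AB effect from the AC effect through the common
comparator A, assuming relative effects are constant across trial
populations.  Population-adjusted comparisons replace the AB effect
with one predicted for the AC population (anchored), or contrast
predicted absolute outcomes directly (unanchored — far stronger
assumptions).  Under the shared effect modifier assumption a B-vs-C
contrast is population-invariant and may be relabelled to any target
population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .data import ArmSummary, CovariateSpec, TargetPopulation
from .scales import Scale, get_scale

logger = logging.getLogger("popadjust")

__all__ = [
    "TrialEffect",
    "ComparisonResult",
    "trial_relative_effect",
    "bucher",
    "anchored_comparison",
    "unanchored_comparison",
    "transport_effect",
    "absolute_effects",
    "check_assumptions",
    "UNANCHORED_WARNING",
    "CONSTANCY_WARNING",
    "SHARED_EM_WARNING",
]

UNANCHORED_WARNING = (
    "unanchored comparison: conditional constancy of absolute effects is "
    "assumed — every prognostic variable and effect modifier must be "
    "accounted for, and residual systematic bias is unquantified"
)
CONSTANCY_WARNING = (
    "standard indirect comparison: constancy of relative effects across "
    "trial populations is assumed (no effect-modifier imbalance)"
)
SHARED_EM_WARNING = (
    "shared effect modifier assumption invoked: requires clinical/biological "
    "justification that the treatments share identical effect modifiers and "
    "interaction coefficients (more plausible within a treatment class)"
)


@dataclass(frozen=True)
class TrialEffect:
    """A relative effect on the linear-predictor scale."""

    contrast: tuple  # (treatment, reference), e.g. ("B", "A")
    population: str
    scale: Scale
    estimate: float
    se: float

    def __post_init__(self):
        if not np.isfinite(self.estimate):
            raise ValueError("estimate must be finite")
        if not (self.se > 0 or np.isnan(self.se)):
            raise ValueError("se must be positive")

    @property
    def ci95(self):
        h = 1.959963984540054 * self.se
        return (self.estimate - h, self.estimate + h)


@dataclass(frozen=True)
class ComparisonResult:
    """An indirect comparison with its provenance made explicit."""

    contrast: tuple
    population: str
    scale: Scale
    estimate: float
    se: float
    anchored: bool
    method: str  # bucher | maic | maic_entropy | stc | ...
    shared_em_used: bool = False
    warnings: tuple = ()
    ess: Optional[float] = None

    def __post_init__(self):
        if not self.population:
            raise ValueError("the target population must be explicitly stated")
        if not self.anchored and UNANCHORED_WARNING not in self.warnings:
            object.__setattr__(
                self, "warnings", tuple(self.warnings) + (UNANCHORED_WARNING,)
            )

    @property
    def ci95(self):
        h = 1.959963984540054 * self.se
        return (self.estimate - h, self.estimate + h)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        g_inv = self.scale.g_inv
        return {
            "contrast": f"{self.contrast[0]} vs {self.contrast[1]}",
            "population": self.population,
            "scale": self.scale.name,
            "estimate": self.estimate,
            "se": self.se,
            "ci95": [lo, hi],
            "natural_scale_estimates": None
            if self.scale.name == "identity"
            else {
                "exp_estimate": float(np.exp(self.estimate)),
                "exp_ci95": [float(np.exp(lo)), float(np.exp(hi))],
            },
            "anchored": self.anchored,
            "method": self.method,
            "shared_em_used": self.shared_em_used,
            "ess": self.ess,
            "warnings": list(self.warnings),
        }


def _linked_arm(a: ArmSummary, scale: Scale, continuity: bool = True):
    """g(ybar) and its delta-method SE, with a 0.5 continuity correction
    for binary arms sitting on the domain boundary."""
    ybar, se, n = a.ybar, a.se_ybar, a.n
    if continuity and scale.name in ("log", "logit") and ybar in (0.0, 1.0):
        r = ybar * n
        ybar = (r + 0.5) / (n + 1)
        se = float(np.sqrt(ybar * (1 - ybar) / n))
        logger.warning(
            "arm %s: boundary proportion; 0.5 continuity correction applied",
            a.arm,
        )
    g_y = float(scale.link(ybar))
    se_g = float(abs(scale.dg(ybar)) * se) if se is not None else np.nan
    return g_y, se_g


def trial_relative_effect(
    a1: ArmSummary,
    a0: ArmSummary,
    scale="identity",
    population: str = "",
) -> TrialEffect:
    """Within-trial relative effect ``g(ybar_1) - g(ybar_0)``.

    The SE is by the delta method,
    ``sqrt(dg(y1)^2 se1^2 + dg(y0)^2 se0^2)`` (independent arms).
    """
    scale = get_scale(scale)
    g1, s1 = _linked_arm(a1, scale)
    g0, s0 = _linked_arm(a0, scale)
    se = float(np.sqrt(s1**2 + s0**2))
    return TrialEffect(
        contrast=(a1.arm, a0.arm),
        population=population or "trial",
        scale=scale,
        estimate=g1 - g0,
        se=se,
    )


def bucher(d_ac: TrialEffect, d_ab: TrialEffect) -> ComparisonResult:
    """Standard anchored indirect comparison through the common comparator.

    ``est = est_AC - est_AB``; variances add (independent trials).  The
    population is labelled ``assumed-constant`` to surface the constancy
    assumption rather than leave it implicit.
    """
    if d_ac.scale.name != d_ab.scale.name:
        raise ValueError(
            f"scale mismatch: {d_ac.scale.name} vs {d_ab.scale.name}"
        )
    if d_ac.contrast[1] != d_ab.contrast[1]:
        raise ValueError(
            "contrasts must share the anchor treatment "
            f"({d_ac.contrast[1]!r} vs {d_ab.contrast[1]!r})"
        )
    return ComparisonResult(
        contrast=(d_ac.contrast[0], d_ab.contrast[0]),
        population="assumed-constant",
        scale=d_ac.scale,
        estimate=d_ac.estimate - d_ab.estimate,
        se=float(np.sqrt(d_ac.se**2 + d_ab.se**2)),
        anchored=True,
        method="bucher",
        warnings=(CONSTANCY_WARNING,),
    )


def anchored_comparison(
    pred_A: ArmSummary,
    pred_B: ArmSummary,
    obs_A: ArmSummary,
    obs_C: ArmSummary,
    scale="identity",
    population: str = "AC",
    method: str = "maic",
    se_ab: Optional[float] = None,
    ess: Optional[float] = None,
    warnings: Sequence[str] = (),
) -> ComparisonResult:
    """Population-adjusted anchored comparison.

    ``est = (g(ybar_C) - g(ybar_A)) - (g(yhat_B) - g(yhat_A))`` where the
    predictions come from weighting or outcome regression in the AC
    population.  ``se_ab`` overrides the delta-method SE of the
    predicted AB contrast (pass the sandwich or bootstrap SE here);
    AC-arm and AB-prediction uncertainties add as independent.
    """
    scale = get_scale(scale)
    d_ac = trial_relative_effect(obs_C, obs_A, scale, population)
    d_ab_pred = trial_relative_effect(pred_B, pred_A, scale, population)
    se_pred = se_ab if se_ab is not None else d_ab_pred.se
    return ComparisonResult(
        contrast=(obs_C.arm, pred_B.arm),
        population=population,
        scale=scale,
        estimate=d_ac.estimate - d_ab_pred.estimate,
        se=float(np.sqrt(d_ac.se**2 + se_pred**2)),
        anchored=True,
        method=method,
        ess=ess,
        warnings=tuple(warnings),
    )


def unanchored_comparison(
    pred_B: ArmSummary,
    obs_C: ArmSummary,
    scale="identity",
    population: str = "AC",
    method: str = "maic",
    se_b: Optional[float] = None,
    ess: Optional[float] = None,
    anchored_available: bool = False,
    warnings: Sequence[str] = (),
) -> ComparisonResult:
    """Unanchored comparison ``g(ybar_C) - g(yhat_B)``.

    Refused outright when an anchored route is available: anchored
    comparisons preserve within-trial randomisation and must always be
    preferred in a connected network.
    """
    if anchored_available:
        raise ValueError(
            "an anchored comparison route is available; unanchored "
            "comparisons may only be considered in the absence of a "
            "connected network of randomized evidence"
        )
    scale = get_scale(scale)
    g_c, se_c = _linked_arm(obs_C, scale)
    g_b, se_b_delta = _linked_arm(pred_B, scale)
    se_pred = se_b if se_b is not None else se_b_delta
    return ComparisonResult(
        contrast=(obs_C.arm, pred_B.arm),
        population=population,
        scale=scale,
        estimate=g_c - g_b,
        se=float(np.sqrt(se_c**2 + se_pred**2)),
        anchored=False,
        method=method,
        ess=ess,
        warnings=tuple(warnings),
    )


def transport_effect(
    result: ComparisonResult,
    target: TargetPopulation,
    shared_em: bool = False,
    treatment_set: Sequence[str] = (),
) -> ComparisonResult:
    """Relabel a contrast to a new target population.

    Valid only under the shared effect modifier assumption for a
    declared treatment set containing both members of the contrast:
    then ``d_tu(P) = d_tu(Q)`` for any populations P, Q and the
    estimate transports unchanged.
    """
    if target.label == result.population:
        return result
    if not shared_em:
        raise ValueError(
            f"cannot transport the estimate from population "
            f"{result.population!r} to {target.label!r} without the shared "
            "effect modifier assumption"
        )
    missing = [t for t in result.contrast if t not in set(treatment_set)]
    if missing:
        raise ValueError(
            f"treatment(s) {missing} not in the declared shared-effect-"
            f"modifier set {sorted(set(treatment_set))}"
        )
    return replace(
        result,
        population=target.label,
        shared_em_used=True,
        warnings=tuple(result.warnings)
        + ((SHARED_EM_WARNING,) if SHARED_EM_WARNING not in result.warnings else ()),
    )


def absolute_effects(
    target: TargetPopulation,
    d_ab: Optional[TrialEffect] = None,
    d_ac: Optional[TrialEffect] = None,
    scale="identity",
) -> dict:
    """Back-calculate absolute outcomes in the target population.

    ``yhat_t(P) = g^{-1}(g(ybar_A(P)) + d_At(P))``.  SEs by the delta
    method treating the external baseline and the contrasts as
    independent.
    """
    scale = get_scale(scale)
    if target.baseline_A is None:
        raise ValueError(
            f"population {target.label}: baseline outcome on A is required "
            "before absolute effects can be produced"
        )
    base = target.baseline_A
    g_a, se_ga = _linked_arm(base, scale)
    out = {"A": ArmSummary(arm="A", n=base.n, ybar=base.ybar, se_ybar=base.se_ybar)}
    for eff, label in ((d_ab, "B"), (d_ac, "C")):
        if eff is None:
            continue
        if eff.population != target.label:
            raise ValueError(
                f"relative effect labelled for population {eff.population!r}, "
                f"not the target {target.label!r}"
            )
        if eff.scale.name != scale.name:
            raise ValueError("scale mismatch between contrast and request")
        eta = g_a + eff.estimate
        y = float(scale.g_inv(eta))
        var_eta = (0.0 if np.isnan(se_ga) else se_ga**2) + eff.se**2
        # d g^{-1}(eta)/d eta = 1 / dg(y)
        se_y = float(np.sqrt(var_eta) / abs(scale.dg(y)))
        out[label] = ArmSummary(arm=label, n=base.n, ybar=y, se_ybar=se_y)
    return out


def check_assumptions(
    method: str,
    spec: Sequence[CovariateSpec],
    anchored: bool,
    adjusted: Sequence[str],
    scale="identity",
    population: str = "AC",
    imbalanced: Optional[Sequence[str]] = None,
) -> list:
    """Rule-based warnings about covariate selection, scale and target.

    * anchored weighting: adjust for **all** effect modifiers (balanced
      or not) and **no** purely prognostic variables (over-matching
      loses precision without reducing bias);
    * anchored outcome regression: every imbalanced effect modifier
      must be in the model;
    * unanchored (either method): all declared effect modifiers *and*
      prognostic variables are required to predict absolute outcomes;
    * every analysis states its scale and its target population.
    """
    scale = get_scale(scale)
    adjusted = set(adjusted)
    ems = {s.name for s in spec if s.is_effect_modifier}
    progs_only = {s.name for s in spec if s.role == "prognostic"}
    warnings_list = []
    weighting = method in ("maic", "maic_entropy", "weighting")
    if anchored:
        if weighting:
            over = sorted(adjusted & progs_only)
            if over:
                warnings_list.append(
                    f"over-matching: purely prognostic covariate(s) {over} are "
                    "matched; this loses precision without reducing bias"
                )
            missing_em = sorted(ems - adjusted)
            if missing_em:
                warnings_list.append(
                    f"effect modifier(s) {missing_em} are not adjusted for; "
                    "anchored weighting should adjust for all effect modifiers, "
                    "in imbalance or not"
                )
        else:  # outcome regression
            imb = set(imbalanced) if imbalanced is not None else ems
            missing_em = sorted((ems & imb) - adjusted)
            if missing_em:
                warnings_list.append(
                    f"imbalanced effect modifier(s) {missing_em} excluded from "
                    "the outcome model; bias is not removed"
                )
    else:
        missing = sorted((ems | progs_only) - adjusted)
        if missing:
            warnings_list.append(
                f"unanchored analysis omits declared covariate(s) {missing}; "
                "conditional constancy of absolute effects requires all "
                "effect modifiers and prognostic variables"
            )
    warnings_list.append(
        f"comparison carried out on the {scale.name} linear predictor scale"
    )
    warnings_list.append(f"target population: {population}")
    return warnings_list
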