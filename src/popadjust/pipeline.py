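"""End-to-end analysis pipelines: load -> adjust -> compare -> variance.

Each function takes the AB IPD trial and the AC aggregate trial and
returns a :class:`~popadjust.comparison.ComparisonResult` for the B-vs-C
contrast in the AC population.  Covariate selection follows the
anchoring rules: anchored weighting matches effect modifiers only
(matching purely prognostic covariates is over-matching), while
unanchored analyses must adjust for every declared covariate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .comparison import (
    ComparisonResult,
    anchored_comparison,
    bucher,
    check_assumptions,
    trial_relative_effect,
    unanchored_comparison,
)
from .data import AggregateTrial, CovariateSpec, IPDTrial, summarize_ipd
from .maic import (
    MAICWeighter,
    WeightSolution,
    build_moment_matrix,
    weighted_arm_estimates,
)
from .stc import CovariateDistribution, STCModel
from .uncertainty import sandwich_se

__all__ = ["bucher_analysis", "maic_analysis", "stc_analysis"]

ANCHORED_ROLES = ("effect_modifier", "both")
ALL_ROLES = ("effect_modifier", "both", "prognostic")


def _observed_arms(agg: AggregateTrial, anchor: str = "A"):
    arms = dict(agg.arm_summaries)
    other = [a for a in arms if a != anchor]
    if anchor not in arms or len(other) != 1:
        raise ValueError(
            f"aggregate trial must have arm {anchor!r} plus one comparator"
        )
    return arms[anchor], arms[other[0]]


def bucher_analysis(trial: IPDTrial, aggregate: AggregateTrial, scale="identity"):
    """Standard indirect comparison with no population adjustment."""
    _, ab_arms = summarize_ipd(trial)
    arms = trial.arms
    d_ab = trial_relative_effect(
        ab_arms[arms[1]], ab_arms[arms[0]], scale, population=trial.trial_id
    )
    obs_a, obs_c = _observed_arms(aggregate)
    d_ac = trial_relative_effect(obs_c, obs_a, scale, population=aggregate.trial_id)
    return bucher(d_ac, d_ab)


def maic_analysis(
    trial: IPDTrial,
    aggregate: AggregateTrial,
    scale="identity",
    anchored: bool = True,
    method: str = "moments",
    spec: Optional[Sequence[CovariateSpec]] = None,
    selection: Optional[Sequence[str]] = None,
    variance: str = "sandwich",
) -> ComparisonResult:
    """Weighting-based population-adjusted comparison in the AC population."""
    spec = list(spec) if spec is not None else list(trial.spec)
    if selection is None:
        selection = ANCHORED_ROLES if anchored else ALL_ROLES
    selected = [s for s in spec if s.role in set(selection)]
    if selected:
        Z = build_moment_matrix(
            trial, aggregate.covariate_summaries, spec=spec, selection=selection
        )
        sol = MAICWeighter(method=method).fit(Z).solution()
    else:
        # nothing to match (e.g. anchored analysis with no declared effect
        # modifiers): weights are uniform and no adjustment occurs
        Z = None
        sol = WeightSolution(
            alpha=np.zeros(0),
            weights=np.ones(trial.n),
            ess=float(trial.n),
            converged=True,
            gradient_norm=0.0,
            method=method,
        )
    pred = weighted_arm_estimates(trial, sol)
    arms = trial.arms
    obs_a, obs_c = _observed_arms(aggregate)
    se_ab = (
        sandwich_se(sol, trial, Z, scale).se_total if variance == "sandwich" else None
    )
    adjusted = sorted({lab.split(":")[0] for lab in sol.column_labels})
    label = "maic" if method == "moments" else "maic_entropy"
    warn = check_assumptions(
        label, spec, anchored, adjusted, scale, population=aggregate.trial_id
    )
    if anchored:
        return anchored_comparison(
            pred[arms[0]],
            pred[arms[1]],
            obs_a,
            obs_c,
            scale,
            population=aggregate.trial_id,
            method=label,
            se_ab=se_ab,
            ess=sol.ess,
            warnings=warn,
        )
    return unanchored_comparison(
        pred[arms[1]],
        obs_c,
        scale,
        population=aggregate.trial_id,
        method=label,
        ess=sol.ess,
        warnings=warn,
    )


def stc_analysis(
    trial: IPDTrial,
    aggregate: AggregateTrial,
    scale="identity",
    anchored: bool = True,
    prediction: str = "plugin",
    n_draws: int = 100_000,
    seed: Optional[int] = None,
    spec: Optional[Sequence[CovariateSpec]] = None,
) -> ComparisonResult:
    """Outcome-regression population-adjusted comparison in the AC population."""
    if spec is not None and list(spec) != list(trial.spec):
        trial = IPDTrial(
            trial_id=trial.trial_id,
            data=trial.data,
            spec=list(spec),
            outcome_type=trial.outcome_type,
            arm_col=trial.arm_col,
            outcome_col=trial.outcome_col,
        )
    model = STCModel(scale=scale).fit(trial)
    model_names = {s.name for s in trial.spec}
    target = [c for c in aggregate.covariate_summaries if c.name in model_names]
    if prediction == "plugin":
        pred, info = model.predict_plugin(target)
    elif prediction == "simulate":
        dist = CovariateDistribution.from_marginals(target, trial.spec, ipd=trial)
        pred, info = model.predict_by_simulation(dist, n_draws=n_draws, seed=seed)
    else:
        raise ValueError(f"unknown prediction route {prediction!r}")
    arms = trial.arms
    obs_a, obs_c = _observed_arms(aggregate)
    adjusted = [s.name for s in trial.spec]
    label = "stc" if prediction == "plugin" else "stc_simulate"
    warn = check_assumptions(
        label, trial.spec, anchored, adjusted, scale, population=aggregate.trial_id
    ) + list(info.get("warnings", ()))
    if anchored:
        return anchored_comparison(
            pred[arms[0]],
            pred[arms[1]],
            obs_a,
            obs_c,
            scale,
            population=aggregate.trial_id,
            method=label,
            se_ab=info["se_contrast"],
            warnings=warn,
        )
    # unanchored STC: SE of the absolute B prediction from the coefficient
    # covariance via the gradient of the linear predictor at the target
    by_name = {t.name: t for t in target}
    xbar = np.array([by_name[nm].mean for nm in model.names_]) - model.offset_
    em_idx = [model.names_.index(nm) for nm in model.em_names_]
    c = np.concatenate([[1.0], xbar, [1.0], xbar[em_idx]])
    se_eta = float(np.sqrt(c @ model.vcov_ @ c))  # SE of g(yhat_B), link scale
    return unanchored_comparison(
        pred[arms[1]],
        obs_c,
        scale,
        population=aggregate.trial_id,
        method=label,
        se_b=se_eta,
        warnings=warn,
    )
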