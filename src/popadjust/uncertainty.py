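"""Variance estimation for population-adjusted estimates.

Weights estimated by moment matching are not fixed quantities; naive
fixed-weight standard errors ignore that.  The sandwich here stacks the
moment-balance estimating equations for the weight coefficients with
the weighted-mean equations for the two AB arm means and applies
standard M-estimation theory, ``Var = A^{-1} B A^{-T}``, with the
B-vs-A contrast on the link scale obtained by the delta method.  A
nonparametric bootstrap (resampling AB patients within arm, and
parametrically redrawing the AC summaries) is provided as a generic
cross-check for any analysis pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .data import AggregateTrial, ArmSummary, IPDTrial
from .maic import MomentMatrix, WeightSolution
from .scales import Scale, get_scale

logger = logging.getLogger("popadjust")

__all__ = ["VarianceReport", "sandwich_se", "bootstrap"]


@dataclass
class VarianceReport:
    """Standard-error breakdown for a comparison estimate."""

    se_total: float
    se_components: dict = field(default_factory=dict)
    method: str = "sandwich"
    n_boot: Optional[int] = None
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)


def sandwich_se(
    w: WeightSolution,
    trial: IPDTrial,
    Z: Optional[MomentMatrix] = None,
    scale="identity",
) -> VarianceReport:
    """Robust sandwich SE for the weighted B-vs-A contrast on the link scale.

    Parameters
    ----------
    w : WeightSolution
        Converged weight solution (weights aligned with ``trial`` rows).
    trial : IPDTrial
        The AB trial the weights were estimated on.
    Z : MomentMatrix, optional
        The centered moment matrix used for fitting.  ``None`` means no
        moments were matched (fixed uniform weights), in which case the
        sandwich reduces to the classical robust SE of each arm mean.
    scale : str or Scale
        Link for the contrast ``g(mu_B) - g(mu_A)``.

    Returns
    -------
    VarianceReport with ``se_total`` the SE of the linked contrast and
    per-arm components.
    """
    scale = get_scale(scale)
    y = trial.outcomes
    n = trial.n
    wt = np.asarray(w.weights, dtype=float)
    if len(wt) != n:
        raise ValueError("weights not aligned with trial rows")
    Zmat = (
        Z.Z if isinstance(Z, MomentMatrix) else np.asarray(Z, dtype=float)
    ) if Z is not None else np.empty((n, 0))
    k = Zmat.shape[1]

    arms = trial.arms
    m_a = trial.arm_mask(arms[0]).astype(float)
    m_b = trial.arm_mask(arms[1]).astype(float)
    mu_a = float(np.sum(y * wt * m_a) / np.sum(wt * m_a))
    mu_b = float(np.sum(y * wt * m_b) / np.sum(wt * m_b))

    # stacked estimating equations, theta = (alpha, mu_A, mu_B):
    #   psi_alpha,i = z_i w_i                 (moment balance)
    #   psi_muA,i   = 1A_i w_i (y_i - mu_A)   (weighted-mean equation)
    #   psi_muB,i   = 1B_i w_i (y_i - mu_B)
    resid_a = m_a * wt * (y - mu_a)
    resid_b = m_b * wt * (y - mu_b)
    psi = np.column_stack([Zmat * wt[:, None], resid_a, resid_b])

    p = k + 2
    A = np.zeros((p, p))
    if k:
        A[:k, :k] = (Zmat * wt[:, None]).T @ Zmat
        A[k, :k] = resid_a @ Zmat
        A[k + 1, :k] = resid_b @ Zmat
    A[k, k] = -np.sum(wt * m_a)
    A[k + 1, k + 1] = -np.sum(wt * m_b)
    B = psi.T @ psi
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular Jacobian in the sandwich; check weight convergence "
            "and moment-matrix rank"
        ) from None
    V = Ainv @ B @ Ainv.T

    # delta method for g(mu_B) - g(mu_A)
    h = np.zeros(p)
    h[k] = -float(scale.dg(mu_a))
    h[k + 1] = float(scale.dg(mu_b))
    var_contrast = float(h @ V @ h)
    se_a = float(np.sqrt(max(V[k, k], 0.0)))
    se_b = float(np.sqrt(max(V[k + 1, k + 1], 0.0)))
    return VarianceReport(
        se_total=float(np.sqrt(max(var_contrast, 0.0))),
        se_components={
            f"mu_{arms[0]}": se_a,
            f"mu_{arms[1]}": se_b,
        },
        method="sandwich",
        extra={"mu": {arms[0]: mu_a, arms[1]: mu_b}, "vcov_dim": p},
    )


def _resample_aggregate(agg: AggregateTrial, rng: np.random.Generator):
    """Parametric redraw of the AC arm summaries."""
    arms = {}
    for name, a in agg.arm_summaries.items():
        if agg.outcome_type == "binary":
            r = rng.binomial(int(a.n), a.ybar)
            ybar = r / a.n
            se = float(np.sqrt(max(ybar * (1 - ybar), 0.0) / a.n))
        else:
            ybar = float(rng.normal(a.ybar, a.se_ybar))
            se = a.se_ybar
        arms[name] = ArmSummary(arm=a.arm, n=a.n, ybar=ybar, se_ybar=se)
    return AggregateTrial(
        trial_id=agg.trial_id,
        arm_summaries=arms,
        covariate_summaries=agg.covariate_summaries,
        outcome_type=agg.outcome_type,
    )


def bootstrap(
    analysis: Callable[[IPDTrial, AggregateTrial], float],
    trial: IPDTrial,
    aggregate: AggregateTrial,
    n_boot: int = 1000,
    seed: int = 0,
    resample_aggregate: bool = True,
) -> VarianceReport:
    """Bootstrap SE/CIs for an arbitrary analysis pipeline.

    ``analysis`` maps a (resampled) AB trial plus a (redrawn) AC
    aggregate to a point estimate.  AB patients are resampled with
    replacement within each arm; AC summaries are redrawn
    parametrically.  Replicates where the analysis raises (for example
    non-convergent weights on a bad resample) are dropped and counted;
    more than 10% failures aborts with a diagnostic.

    Per-replicate RNG streams are spawned from the master seed by a
    counter, so results do not depend on execution order.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    df = trial.data
    arm_idx = {arm: np.flatnonzero(trial.arm_mask(arm)) for arm in trial.arms}
    estimates = []
    failures = 0
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_boot)
    for b in range(n_boot):
        rng = np.random.default_rng(children[b])
        rows = np.concatenate(
            [rng.choice(idx, size=len(idx), replace=True) for idx in arm_idx.values()]
        )
        boot_trial = IPDTrial(
            trial_id=trial.trial_id,
            data=df.iloc[rows].reset_index(drop=True),
            spec=trial.spec,
            outcome_type=trial.outcome_type,
            arm_col=trial.arm_col,
            outcome_col=trial.outcome_col,
        )
        boot_agg = (
            _resample_aggregate(aggregate, rng) if resample_aggregate else aggregate
        )
        try:
            estimates.append(float(analysis(boot_trial, boot_agg)))
        except Exception as exc:  # noqa: BLE001 - replicate-level failure
            failures += 1
            logger.debug("bootstrap replicate %d failed: %s", b, exc)
    if failures > 0.1 * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed; the weight "
            "model is unstable on resampled data (poor overlap?)"
        )
    est = np.asarray(estimates)
    se = float(est.std(ddof=1))
    lo, hi = np.percentile(est, [2.5, 97.5])
    mean = float(est.mean())
    return VarianceReport(
        se_total=se,
        se_components={"bootstrap": se},
        method="bootstrap",
        n_boot=n_boot,
        seed=seed,
        extra={
            "percentile_ci95": [float(lo), float(hi)],
            "normal_ci95": [mean - 1.959963984540054 * se, mean + 1.959963984540054 * se],
            "failed_replicates": failures,
            "mean": mean,
        },
    )
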