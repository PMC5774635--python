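"""Matching-adjusted weighting of IPD to an aggregate population.

The weight model is log-linear in the covariates, ``log w_i = a0 +
a1' x_i``, interpreted as the odds of enrolment in the aggregate (AC)
trial versus the IPD (AB) trial.  With covariates centered at the AC
targets the method-of-moments estimate of ``a1`` is the minimiser of
the convex objective ``sum_i exp(a1' z_i)``; at the optimum the
weighted mean of every matched moment equals its published target
exactly.  The intercept ``a0`` is never estimated: it cancels from all
weighted averages, and weights are reported normalised to sum to N.

Entropy balancing solves the Lagrangian dual of "keep weights as close
to uniform as possible subject to the same moment constraints"; both
routes live in the same exponential family and coincide, but they are
implemented independently so the coincidence can serve as a check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .data import ArmSummary, CovariateSpec, CovariateSummary, IPDTrial

logger = logging.getLogger("popadjust")

__all__ = [
    "MomentMatrix",
    "WeightSolution",
    "MAICWeighter",
    "build_moment_matrix",
    "fit_maic_weights",
    "fit_entropy_weights",
    "weighted_arm_estimates",
    "effective_sample_size",
    "weight_summary",
]

ESS_CAVEAT = (
    "The (sum w)^2 / sum(w^2) approximation assumes fixed, known weights "
    "and is likely to be an underestimation of the true ESS."
)


class SupportError(ValueError):
    """A target moment lies outside the observed covariate support."""


@dataclass
class MomentMatrix:
    """Centered moment columns for the weight model.

    Each column of ``Z`` is a covariate moment minus its aggregate-trial
    target: mean columns are ``x - mean_target``; variance-matched
    continuous covariates add a second-raw-moment column
    ``x^2 - (mean^2 + sd^2)``.  A weighted mean of the raw moments
    equals its target iff the weighted mean of the Z column is zero.
    """

    Z: np.ndarray
    column_labels: list
    targets: dict = field(default_factory=dict)  # label -> raw target value
    raw_columns: Optional[np.ndarray] = None  # uncentered moments, same order

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def k(self) -> int:
        return self.Z.shape[1]


def build_moment_matrix(
    trial: IPDTrial,
    target: Sequence[CovariateSummary],
    spec: Optional[Sequence[CovariateSpec]] = None,
    selection: Optional[Sequence[str]] = None,
) -> MomentMatrix:
    """Assemble the centered moment matrix for ``trial`` against ``target``.

    Parameters
    ----------
    trial : IPDTrial
        The AB trial supplying patient-level covariates (both arms pooled).
    target : sequence of CovariateSummary
        Published summaries of the aggregate population.
    spec : sequence of CovariateSpec, optional
        Covariate roles/moment choices; defaults to ``trial.spec``.
    selection : sequence of str, optional
        Roles to include, e.g. ``("effect_modifier", "both")`` for an
        anchored analysis, or all roles for an unanchored one.  ``None``
        includes every covariate in the spec.
    """
    spec = list(spec) if spec is not None else list(trial.spec)
    target_by_name = {t.name: t for t in target}
    if selection is not None:
        selection = set(selection)
        spec = [s for s in spec if s.role in selection]
    if not spec:
        raise ValueError("no covariates selected for moment matching")

    cols, labels, targets, raw = [], [], {}, []
    for s in spec:
        if s.name not in target_by_name:
            raise ValueError(f"no target summary for covariate {s.name!r}")
        t = target_by_name[s.name]
        x = trial.data[s.name].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if not lo < t.mean < hi:
            if not (lo <= t.mean <= hi and lo < hi):
                raise SupportError(
                    f"target mean {t.mean} for {s.name!r} not within the "
                    f"observed support [{lo}, {hi}]: no weight set can "
                    "balance it"
                )
        cols.append(x - t.mean)
        labels.append(f"{s.name}:mean")
        targets[f"{s.name}:mean"] = t.mean
        raw.append(x)
        if s.kind == "continuous" and s.match_moments == "mean_and_variance":
            if t.sd is None:
                raise ValueError(
                    f"{s.name}: variance matching requires a target sd"
                )
            m2 = t.mean**2 + t.sd**2  # second raw moment E[X^2] = mu^2 + sd^2
            x2 = x**2
            if not x2.min() < m2 < x2.max():
                raise SupportError(
                    f"target second moment {m2:.4g} for {s.name!r} not "
                    "within the observed support of x^2"
                )
            cols.append(x2 - m2)
            labels.append(f"{s.name}:second_moment")
            targets[f"{s.name}:second_moment"] = m2
            raw.append(x2)

    Z = np.column_stack(cols)
    raw = np.column_stack(raw)

    # rank-revealing QR: drop dependent columns with a warning naming them
    q, r, piv = scipy.linalg.qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < Z.shape[1]:
        drop = sorted(piv[rank:])
        dropped = [labels[j] for j in drop]
        warnings.warn(
            f"collinear moment column(s) removed: {dropped}", stacklevel=2
        )
        keep = sorted(piv[:rank])
        Z = Z[:, keep]
        raw = raw[:, keep]
        labels = [labels[j] for j in keep]
    return MomentMatrix(Z=Z, column_labels=labels, targets=targets, raw_columns=raw)


@dataclass
class WeightSolution:
    """Fitted weights with diagnostics.

    ``alpha`` is on the raw covariate scale (one entry per moment
    column); weights are normalised to sum to N.
    """

    alpha: np.ndarray
    weights: np.ndarray
    ess: float
    converged: bool
    gradient_norm: float
    method: str
    column_labels: list = field(default_factory=list)
    n_iter: int = 0

    @property
    def n(self) -> int:
        return len(self.weights)


def effective_sample_size(weights) -> float:
    """Kish effective sample size ``(sum w)^2 / sum(w^2)``.

    Invariant to rescaling of the weights; equals N iff all weights are
    equal (Cauchy-Schwarz).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    s = w.sum()
    if s <= 0:
        raise ValueError("all-zero weights have no effective sample size")
    return float(s**2 / np.sum(w**2))


class MAICWeighter(BaseEstimator):
    """Method-of-moments / entropy-balancing weight estimator.

    scikit-learn style: construct with hyper-parameters, ``fit`` on a
    centered moment matrix, read fitted attributes (trailing
    underscore).  Both AB arms are pooled during fitting, matching the
    double sum in the moment-matching objective.

    Parameters
    ----------
    method : {"moments", "entropy"}
        ``moments``: Newton minimisation of ``sum exp(a'z)`` with
        analytic gradient/Hessian and backtracking line search,
        falling back to BFGS if Newton stalls.
        ``entropy``: BFGS on the entropy-balancing dual
        ``log sum exp(l'z)``.
    tol : float
        Convergence tolerance on the infinity-norm of the balance
        residual (the weighted mean of each centered column).
    max_iter : int
        Newton iteration cap.

    Attributes
    ----------
    alpha_ : ndarray of shape (k,)
        Weight-model coefficients on the raw moment scale.
    weights_ : ndarray of shape (n,)
        Weights normalised to sum to n.
    ess_ : float
        Effective sample size of the weighted pseudo-population.
    converged_ : bool
    gradient_norm_ : float
        Infinity-norm of the balance residual at the solution.
    """

    def __init__(self, method: str = "moments", tol: float = 1e-11, max_iter: int = 200):
        self.method = method
        self.tol = tol
        self.max_iter = max_iter

    # -- internals ----------------------------------------------------
    @staticmethod
    def _standardize(Z):
        scale = Z.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        return Z / scale, scale

    def _fit_moments(self, Zs):
        """Damped Newton on f(a) = sum_i exp(Zs_i . a).

        The objective is smooth and strictly convex on a full-rank Z;
        backtracking guards the global phase and full Newton steps are
        taken near the optimum (where a float-equal objective would
        otherwise stall the line search).
        """
        n, k = Zs.shape
        alpha = np.zeros(k)
        trajectory = []
        resid = np.inf
        for it in range(self.max_iter):
            eta = Zs @ alpha
            shift = eta.max()  # overflow guard; preserves the argmin
            w = np.exp(eta - shift)
            grad = Zs.T @ w
            resid = np.abs(grad / w.sum()).max()
            trajectory.append(float(np.linalg.norm(alpha)))
            if resid < self.tol:
                return alpha, True, resid, it
            H = (Zs * w[:, None]).T @ Zs
            try:
                step = np.linalg.solve(H, -grad)
            except np.linalg.LinAlgError:
                break
            f0 = w.sum()
            t = 1.0
            for _ in range(60):
                if np.exp(Zs @ (alpha + t * step) - shift).sum() <= f0:
                    break
                t *= 0.5
            alpha = alpha + t * step
        # quasi-Newton fallback on the (bounded) dual, then Newton polish
        res = scipy.optimize.minimize(
            lambda a: logsumexp(Zs @ a),
            alpha,
            jac=lambda a: _softmax_mean(Zs, a),
            method="BFGS",
            options={"gtol": self.tol / 10, "maxiter": 1000},
        )
        alpha, resid = _newton_polish(Zs, res.x, self.tol)
        converged = resid < self.tol
        if not converged:
            logger.warning(
                "weight fit did not converge (balance residual %.3g); "
                "|alpha| trajectory: %s ... possible poor overlap / "
                "near-boundary target",
                resid,
                trajectory[-5:],
            )
        return alpha, converged, resid, self.max_iter

    def _fit_entropy(self, Zs):
        """BFGS on the entropy-balancing dual g(l) = log sum exp(Zs_i . l)."""
        k = Zs.shape[1]
        res = scipy.optimize.minimize(
            lambda a: logsumexp(Zs @ a),
            np.zeros(k),
            jac=lambda a: _softmax_mean(Zs, a),
            method="BFGS",
            options={"gtol": self.tol / 10, "maxiter": 2000},
        )
        alpha, resid = _newton_polish(Zs, res.x, self.tol)
        return alpha, resid < self.tol, resid, int(res.nit)

    # -- sklearn surface ----------------------------------------------
    def fit(self, Z, y=None):
        """Fit weights to a :class:`MomentMatrix` (or plain centered array)."""
        if isinstance(Z, MomentMatrix):
            labels = Z.column_labels
            Zmat = Z.Z
        else:
            Zmat = np.asarray(Z, dtype=float)
            if Zmat.ndim == 1:
                Zmat = Zmat[:, None]
            labels = [f"z{j}" for j in range(Zmat.shape[1])]
        n = Zmat.shape[0]
        Zs, scale = self._standardize(Zmat)
        if self.method == "moments":
            alpha_s, converged, resid, n_iter = self._fit_moments(Zs)
        elif self.method == "entropy":
            alpha_s, converged, resid, n_iter = self._fit_entropy(Zs)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        alpha = alpha_s / scale  # back to the raw moment scale
        eta = Zmat @ alpha
        w = np.exp(eta - eta.max())
        w = w / w.sum() * n
        self.alpha_ = alpha
        self.weights_ = w
        self.ess_ = effective_sample_size(w)
        self.converged_ = bool(converged)
        self.gradient_norm_ = float(resid)
        self.n_iter_ = n_iter
        self.column_labels_ = labels
        return self

    def solution(self) -> WeightSolution:
        """Bundle the fitted attributes as a :class:`WeightSolution`."""
        return WeightSolution(
            alpha=self.alpha_,
            weights=self.weights_,
            ess=self.ess_,
            converged=self.converged_,
            gradient_norm=self.gradient_norm_,
            method=self.method,
            column_labels=list(self.column_labels_),
            n_iter=self.n_iter_,
        )


def _softmax_mean(Z, alpha):
    eta = Z @ alpha
    p = np.exp(eta - logsumexp(eta))
    return Z.T @ p


def _newton_polish(Zs, alpha, tol, max_steps=30):
    """Full Newton steps on the normalised balance equations.

    Near the optimum the softmax-weighted mean of Z contracts
    quadratically, driving the balance residual to float precision.
    """
    best, best_resid = alpha, np.abs(_softmax_mean(Zs, alpha)).max()
    for _ in range(max_steps):
        eta = Zs @ alpha
        p = np.exp(eta - logsumexp(eta))
        grad = Zs.T @ p
        resid = np.abs(grad).max()
        if resid < best_resid:
            best, best_resid = alpha.copy(), resid
        if resid < tol:
            break
        H = (Zs * p[:, None]).T @ Zs - np.outer(grad, grad)
        try:
            alpha = alpha + np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:  # pragma: no cover - singular near fit
            break
    return best, best_resid


def fit_maic_weights(Z, tol: float = 1e-11, max_iter: int = 200) -> WeightSolution:
    """Method-of-moments weights; see :class:`MAICWeighter`."""
    return MAICWeighter("moments", tol=tol, max_iter=max_iter).fit(Z).solution()


def fit_entropy_weights(Z, tol: float = 1e-11) -> WeightSolution:
    """Entropy-balancing weights; see :class:`MAICWeighter`."""
    return MAICWeighter("entropy", tol=tol).fit(Z).solution()


def weighted_arm_estimates(trial: IPDTrial, w: WeightSolution) -> dict:
    """Weighted average outcome per arm: ``sum(Y w) / sum(w)``.

    ``n`` in each returned :class:`~popadjust.data.ArmSummary` is the
    per-arm effective sample size; ``se_ybar`` is the fixed-weight
    robust standard error (use the sandwich or bootstrap for inference
    that accounts for estimated weights).
    """
    if len(w.weights) != trial.n:
        raise ValueError("weights not aligned with trial rows")
    out = {}
    y = trial.outcomes
    for arm in trial.arms:
        mask = trial.arm_mask(arm)
        wa = w.weights[mask]
        total = wa.sum()
        if total < 1e-12:
            raise ValueError(f"arm {arm!r} effectively empty after weighting")
        ybar = float(np.sum(y[mask] * wa) / total)
        se = float(np.sqrt(np.sum(wa**2 * (y[mask] - ybar) ** 2)) / total)
        out[arm] = ArmSummary(
            arm=arm, n=effective_sample_size(wa), ybar=ybar, se_ybar=se
        )
    return out


def weight_summary(w: WeightSolution, n_bins: int = 10) -> dict:
    """Diagnostics on the weight distribution.

    Reports the spread of the weights, the largest individual shares,
    the pooled ESS, and flags a pseudo-population smaller than 10% of
    the original sample.
    """
    wt = np.asarray(w.weights, dtype=float)
    n = len(wt)
    shares = wt / wt.sum()
    top5 = np.sort(shares)[::-1][:5]
    hist, edges = np.histogram(wt, bins=n_bins)
    flags = []
    if w.ess < 0.1 * n:
        flags.append("ESS < 10% of N")
    if not w.converged:
        flags.append("weight fit did not converge")
    return {
        "n": n,
        "min": float(wt.min()),
        "max": float(wt.max()),
        "quantiles": {
            q: float(np.quantile(wt, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        },
        "top5_shares": top5.tolist(),
        "histogram": {"counts": hist.tolist(), "edges": edges.tolist()},
        "ess": w.ess,
        "ess_fraction": w.ess / n,
        "flags": flags,
        "caveat": ESS_CAVEAT,
    }
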