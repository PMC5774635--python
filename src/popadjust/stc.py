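"""Outcome-regression adjustment (simulated treatment comparison).

An outcome model is fitted to the AB individual patient data on a
declared link scale g:

    g(mu_t(X)) = b0 + b1' X + (bB + b2' X_EM) 1{t = B}

where b1 multiplies the *full* covariate vector (prognostic term), bB
is the B-vs-A effect at X = 0, and b2 holds interaction coefficients on
the effect modifiers X_EM (a subvector of X).  Absolute outcomes in the
aggregate (AC) population are then predicted either by plugging in mean
covariate values — exact only for the identity link — or by averaging
model predictions over draws from the joint covariate distribution,
which removes the aggregation bias that plug-in prediction incurs under
non-identity links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .data import ArmSummary, CovariateSpec, CovariateSummary, IPDTrial
from .scales import Scale, get_scale

logger = logging.getLogger("popadjust")

__all__ = [
    "CovariateDistribution",
    "STCModel",
    "fit_outcome_model",
    "predict_plugin",
    "predict_by_simulation",
    "PLUGIN_BIAS_WARNING",
]

PLUGIN_BIAS_WARNING = (
    "plug-in prediction substitutes mean covariate values into a model "
    "with a non-identity link; such estimators are systematically biased "
    "whenever g(.) is not the identity function — prefer simulation-based "
    "prediction"
)


@dataclass
class CovariateDistribution:
    """Joint covariate distribution for simulation-based prediction.

    Marginals come from the aggregate trial's published summaries
    (normal for continuous covariates, Bernoulli for binary); the
    correlation structure is typically copied from the AB IPD because
    the aggregate publication does not report it.  Draws use a Gaussian
    copula: correlated standard normals transformed marginal-by-
    marginal (binary covariates by thresholding at the target
    proportion's normal quantile).
    """

    names: list
    kinds: list  # "continuous" | "binary", aligned with names
    means: np.ndarray
    sds: np.ndarray  # ignored for binary entries
    correlation: np.ndarray
    source: str = "supplied"

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (len(self.names), len(self.names)):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        evals = np.linalg.eigvalsh((R + R.T) / 2)
        if evals.min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        self.correlation = R

    @classmethod
    def from_marginals(
        cls,
        target: Sequence[CovariateSummary],
        spec: Sequence[CovariateSpec],
        ipd: Optional[IPDTrial] = None,
        correlation: Optional[np.ndarray] = None,
    ) -> "CovariateDistribution":
        """Aggregate-trial marginals + correlations imputed from AB IPD."""
        by_name = {t.name: t for t in target}
        names = [s.name for s in spec]
        kinds = [s.kind for s in spec]
        means, sds = [], []
        for s in spec:
            if s.name not in by_name:
                raise ValueError(f"no target summary for covariate {s.name!r}")
            t = by_name[s.name]
            means.append(t.mean)
            if s.kind == "binary":
                sds.append(0.0)
            else:
                if t.sd is None:
                    raise ValueError(
                        f"{s.name}: continuous covariate needs a target sd "
                        "for simulation-based prediction"
                    )
                sds.append(t.sd)
        source = "supplied-correlations"
        if correlation is None:
            if ipd is not None and len(names) > 1:
                correlation = np.corrcoef(ipd.covariate_matrix(names), rowvar=False)
                source = "AC-marginals + AB-correlations"
            else:
                correlation = np.eye(len(names))
                source = "AC-marginals + independence"
        return cls(
            names=names,
            kinds=kinds,
            means=np.array(means),
            sds=np.array(sds),
            correlation=np.asarray(correlation, dtype=float),
            source=source,
        )

    def draw(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Gaussian-copula draw of shape (n_draws, k)."""
        k = len(self.names)
        L = np.linalg.cholesky(
            self.correlation + 1e-12 * np.eye(k)
        )
        z = rng.standard_normal((n_draws, k)) @ L.T
        X = np.empty_like(z)
        for j, kind in enumerate(self.kinds):
            if kind == "binary":
                p = self.means[j]
                # P(Z > qnorm(1-p)) = p
                X[:, j] = (z[:, j] > norm.ppf(1.0 - p)).astype(float)
            else:
                X[:, j] = self.means[j] + self.sds[j] * z[:, j]
        return X


class STCModel(BaseEstimator):
    """Outcome-regression estimator on a declared link scale.

    scikit-learn style: hyper-parameters at construction, ``fit`` on an
    :class:`~popadjust.data.IPDTrial`, fitted attributes with trailing
    underscores, prediction methods for the two STC prediction routes.

    Parameters
    ----------
    scale : str or Scale
        Link used both for fitting and for the subsequent comparison;
        requesting a different comparison scale downstream is refused
        (scale conflicts make the comparison uninterpretable).
    center_at_target : bool
        If True, covariates are centered at the target means before
        fitting, making the fitted B-vs-A main effect directly the
        effect in the target population.  Off by default.

    Attributes
    ----------
    beta0_ : float                  intercept
    beta1_ : ndarray (k,)           prognostic coefficients (full X)
    beta_b_ : float                 B-vs-A effect at X = 0
    beta2_ : ndarray (k_em,)        effect-modifier interactions
    vcov_ : ndarray                 coefficient covariance matrix
    fit_stats_ : dict               AIC / deviance / residual summaries
    """

    def __init__(self, scale="identity", center_at_target: bool = False):
        self.scale = scale
        self.center_at_target = center_at_target

    # -- design matrix ------------------------------------------------
    @staticmethod
    def _design(X, treat, em_idx):
        cols = [np.ones(len(treat)), *X.T, treat]
        cols += [X[:, j] * treat for j in em_idx]
        return np.column_stack(cols)

    def fit(self, trial: IPDTrial, y=None, target_means=None):
        scale = get_scale(self.scale)
        if trial.outcome_type == "binary" and scale.name == "identity":
            logger.info("identity link on a binary outcome: risk-difference scale")
        if trial.outcome_type == "continuous" and scale.name == "logit":
            raise ValueError("logit link is incompatible with a continuous outcome")

        names = [s.name for s in trial.spec]
        em_names = [s.name for s in trial.spec if s.is_effect_modifier]
        em_idx = [names.index(nm) for nm in em_names]
        X = trial.covariate_matrix(names)
        arms = trial.arms
        treat = (trial.data[trial.arm_col] == arms[1]).to_numpy(dtype=float)
        k = X.shape[1]
        n_coef = 2 + k + len(em_idx)
        for arm in arms:
            if trial.arm_mask(arm).sum() < n_coef:
                raise ValueError(
                    f"arm {arm}: fewer patients than coefficients ({n_coef})"
                )

        offset = np.zeros(k)
        if self.center_at_target:
            if target_means is None:
                raise ValueError("center_at_target=True requires target_means")
            offset = np.asarray([target_means[nm] for nm in names], dtype=float)
        D = self._design(X - offset, treat, em_idx)
        y_vec = trial.outcomes

        if trial.outcome_type == "continuous":
            if scale.name != "identity":
                raise ValueError(
                    f"{scale.name} link with Gaussian errors is not supported; "
                    "continuous outcomes use the identity scale"
                )
            res = sm.OLS(y_vec, D).fit()
            fit_stats = {"aic": float(res.aic), "sigma2": float(res.scale)}
        else:
            fam = {
                "logit": sm.families.Binomial(sm.families.links.Logit()),
                "log": sm.families.Binomial(sm.families.links.Log()),
                "identity": sm.families.Binomial(sm.families.links.Identity()),
            }[scale.name]
            for arm_val, lab in ((0.0, arms[0]), (1.0, arms[1])):
                ya = y_vec[treat == arm_val]
                if ya.min() == ya.max():
                    raise ValueError(
                        f"separation: all outcomes identical in arm {lab}; "
                        "the model is not identifiable"
                    )
            res = sm.GLM(y_vec, D, family=fam).fit()
            if not res.converged:
                raise ValueError("outcome model failed to converge")
            fit_stats = {"aic": float(res.aic), "deviance": float(res.deviance)}

        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            raise ValueError(
                f"design matrix rank deficient ({rank} < {D.shape[1]}); "
                "check for constant or duplicated covariates"
            )

        params = np.asarray(res.params, dtype=float)
        self.scale_ = scale
        self.names_ = names
        self.em_names_ = em_names
        self.arms_ = arms
        self.offset_ = offset
        self.beta0_ = float(params[0])
        self.beta1_ = params[1 : 1 + k]
        self.beta_b_ = float(params[1 + k])
        self.beta2_ = params[2 + k :]
        self.vcov_ = np.asarray(res.cov_params(), dtype=float)
        self.fit_stats_ = fit_stats
        self.result_ = res
        self.trial_ = trial
        return self

    # -- linear predictors --------------------------------------------
    def _check_names(self, supplied):
        unknown = set(supplied) - set(self.names_)
        if unknown:
            raise ValueError(f"covariates unknown to the model: {sorted(unknown)}")
        missing = set(self.names_) - set(supplied)
        if missing:
            raise ValueError(f"missing covariate means: {sorted(missing)}")

    def linear_predictors(self, X: np.ndarray):
        """Per-row linear predictors (eta_A, eta_B) for covariate rows X."""
        Xc = X - self.offset_
        em_idx = [self.names_.index(nm) for nm in self.em_names_]
        eta_a = self.beta0_ + Xc @ self.beta1_
        eta_b = eta_a + self.beta_b_ + Xc[:, em_idx] @ self.beta2_
        return eta_a, eta_b

    def _contrast_se(self, x_em: np.ndarray) -> float:
        """SE of (beta_b + beta2' x_em) from the coefficient covariance."""
        k = len(self.names_)
        c = np.zeros(2 + k + len(self.em_names_))
        c[1 + k] = 1.0
        c[2 + k :] = x_em
        return float(np.sqrt(c @ self.vcov_ @ c))

    # -- prediction routes --------------------------------------------
    def predict_plugin(self, target: Sequence[CovariateSummary]):
        """Plug mean covariate values into the fitted model.

        Returns per-arm :class:`~popadjust.data.ArmSummary` objects and
        a warnings list; under a non-identity link the mandatory
        aggregation-bias warning is attached.
        """
        by_name = {t.name: t for t in target}
        self._check_names(by_name)
        xbar = np.array([[by_name[nm].mean for nm in self.names_]])
        eta_a, eta_b = self.linear_predictors(xbar)
        g_inv = self.scale_.g_inv
        x_em = np.array(
            [by_name[nm].mean for nm in self.em_names_]
        ) - self.offset_[[self.names_.index(nm) for nm in self.em_names_]]
        se_contrast = self._contrast_se(x_em)
        warnings_list = []
        if self.scale_.name != "identity":
            warnings_list.append(PLUGIN_BIAS_WARNING)
        ess = {a: float(self.trial_.arm_mask(a).sum()) for a in self.arms_}
        out = {
            self.arms_[0]: ArmSummary(
                arm=self.arms_[0], n=ess[self.arms_[0]], ybar=float(g_inv(eta_a[0]))
            ),
            self.arms_[1]: ArmSummary(
                arm=self.arms_[1], n=ess[self.arms_[1]], ybar=float(g_inv(eta_b[0]))
            ),
        }
        return out, {"se_contrast": se_contrast, "warnings": warnings_list}

    def predict_by_simulation(
        self,
        dist: CovariateDistribution,
        n_draws: int = 100_000,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ):
        """Average model predictions over joint covariate draws.

        Draws ``X*`` from ``dist`` (Gaussian copula), computes
        ``g^{-1}`` of each arm's linear predictor and averages.  The
        Monte-Carlo standard error of each average is reported so the
        user can verify it is negligible; it is *not* folded into the
        comparison SE.
        """
        if n_draws < 10_000:
            raise ValueError("n_draws must be at least 10,000")
        if rng is None:
            if seed is None:
                raise ValueError("supply a seed (or rng) for reproducibility")
            rng = np.random.default_rng(seed)
        if dist.names != self.names_:
            self._check_names(dist.names)
            order = [dist.names.index(nm) for nm in self.names_]
            dist = CovariateDistribution(
                names=[dist.names[j] for j in order],
                kinds=[dist.kinds[j] for j in order],
                means=dist.means[order],
                sds=dist.sds[order],
                correlation=dist.correlation[np.ix_(order, order)],
                source=dist.source,
            )
        X = dist.draw(n_draws, rng)
        eta_a, eta_b = self.linear_predictors(X)
        g_inv = self.scale_.g_inv
        mu_a, mu_b = g_inv(eta_a), g_inv(eta_b)
        mc_se = {
            self.arms_[0]: float(mu_a.std(ddof=1) / np.sqrt(n_draws)),
            self.arms_[1]: float(mu_b.std(ddof=1) / np.sqrt(n_draws)),
        }
        x_em_mean = X[:, [self.names_.index(nm) for nm in self.em_names_]].mean(axis=0)
        se_contrast = self._contrast_se(
            x_em_mean - self.offset_[[self.names_.index(nm) for nm in self.em_names_]]
        )
        out = {
            self.arms_[0]: ArmSummary(
                arm=self.arms_[0],
                n=float(self.trial_.arm_mask(self.arms_[0]).sum()),
                ybar=float(mu_a.mean()),
            ),
            self.arms_[1]: ArmSummary(
                arm=self.arms_[1],
                n=float(self.trial_.arm_mask(self.arms_[1]).sum()),
                ybar=float(mu_b.mean()),
            ),
        }
        return out, {"mc_se": mc_se, "se_contrast": se_contrast, "warnings": []}


# ---------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------

def fit_outcome_model(
    trial: IPDTrial,
    spec: Optional[Sequence[CovariateSpec]] = None,
    scale="identity",
    **kwargs,
) -> STCModel:
    """Fit the interaction outcome model; thin wrapper over :class:`STCModel`."""
    if spec is not None and list(spec) != list(trial.spec):
        trial = IPDTrial(
            trial_id=trial.trial_id,
            data=trial.data,
            spec=list(spec),
            outcome_type=trial.outcome_type,
            arm_col=trial.arm_col,
            outcome_col=trial.outcome_col,
        )
    return STCModel(scale=scale, **kwargs).fit(trial)


def predict_plugin(model: STCModel, target: Sequence[CovariateSummary]):
    return model.predict_plugin(target)


def predict_by_simulation(model: STCModel, dist, n_draws=100_000, seed=None):
    return model.predict_by_simulation(dist, n_draws=n_draws, seed=seed)
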