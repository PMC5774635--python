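"""Domain containers and readers for the two-trial evidence structure.

The canonical layout is one *AB* trial with individual patient data
(IPD) and one *AC* trial for which only published aggregate data are
available: per-arm sample sizes and summary outcomes, plus trial-level
covariate summaries (mean/SD for continuous covariates, proportions for
binary ones).  A comparison may additionally be projected onto an
external target population described by the same kind of summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("popadjust")

__all__ = [
    "CovariateSpec",
    "IPDTrial",
    "ArmSummary",
    "CovariateSummary",
    "AggregateTrial",
    "TargetPopulation",
    "load_ipd",
    "load_aggregate",
    "load_target_population",
    "summarize_ipd",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Declared role of one covariate.

    ``role`` is fixed a priori (clinical grounds), never inferred from
    the data: ``effect_modifier`` covariates alter the relative effect
    on the chosen scale, ``prognostic`` covariates shift outcome levels
    only, ``both`` do both.  ``match_moments`` controls whether MAIC
    balances the mean only or the mean and variance (continuous only).
    """

    name: str
    kind: str = "continuous"  # continuous | binary
    role: str = "effect_modifier"  # effect_modifier | prognostic | both
    match_moments: str = "mean_only"  # mean_only | mean_and_variance

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"{self.name}: kind must be continuous or binary")
        if self.role not in ("effect_modifier", "prognostic", "both"):
            raise ValueError(f"{self.name}: invalid role {self.role!r}")
        if self.match_moments not in ("mean_only", "mean_and_variance"):
            raise ValueError(f"{self.name}: invalid match_moments")
        if self.kind == "binary" and self.match_moments != "mean_only":
            raise ValueError(
                f"{self.name}: binary covariates always match the mean only"
            )

    @property
    def is_effect_modifier(self) -> bool:
        return self.role in ("effect_modifier", "both")

    @property
    def is_prognostic(self) -> bool:
        return self.role in ("prognostic", "both")


@dataclass(frozen=True)
class ArmSummary:
    """Summary absolute outcome for one trial arm."""

    arm: str
    n: float
    ybar: float
    se_ybar: Optional[float] = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"arm {self.arm}: n must be >= 1, got {self.n}")
        if self.se_ybar is not None and self.se_ybar < 0:
            raise ValueError(f"arm {self.arm}: se_ybar must be >= 0")


@dataclass(frozen=True)
class CovariateSummary:
    """Published marginal summary of one covariate: mean (proportion) and SD."""

    name: str
    mean: float
    sd: Optional[float] = None

    def __post_init__(self):
        if self.sd is not None and self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive, got {self.sd}")


@dataclass
class IPDTrial:
    """Individual patient data for a two-arm trial.

    ``data`` holds one row per patient with an ``arm`` column, an
    ``outcome`` column and one column per covariate.  Binary covariates
    and binary outcomes are coded exactly 0/1; no missing values.
    """

    trial_id: str
    data: pd.DataFrame
    spec: Sequence[CovariateSpec]
    outcome_type: str = "continuous"  # continuous | binary
    arm_col: str = "arm"
    outcome_col: str = "outcome"

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self):
        df = self.data
        needed = [self.arm_col, self.outcome_col] + [s.name for s in self.spec]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"trial {self.trial_id}: missing columns {missing}")
        if df[needed].isna().any().any():
            raise ValueError(
                f"trial {self.trial_id}: missing values present; "
                "use load_ipd for complete-case handling"
            )
        arms = self.arms
        if len(arms) != 2:
            raise ValueError(
                f"trial {self.trial_id}: exactly two arms required, got {arms}"
            )
        for arm in arms:
            if (df[self.arm_col] == arm).sum() == 0:  # pragma: no cover
                raise ValueError(f"trial {self.trial_id}: empty arm {arm}")
        if self.outcome_type == "binary":
            y = df[self.outcome_col]
            if not y.isin([0, 1]).all():
                raise ValueError(
                    f"trial {self.trial_id}: binary outcome must be coded 0/1"
                )
        for s in self.spec:
            if s.kind == "binary" and not df[s.name].isin([0, 1]).all():
                raise ValueError(
                    f"trial {self.trial_id}: binary covariate {s.name!r} "
                    "must be coded 0/1"
                )

    # -- accessors ----------------------------------------------------
    @property
    def arms(self) -> list:
        return sorted(self.data[self.arm_col].unique().tolist())

    @property
    def n(self) -> int:
        return len(self.data)

    def arm_mask(self, arm: str) -> np.ndarray:
        if arm not in self.arms:
            raise ValueError(f"trial {self.trial_id}: unknown arm {arm!r}")
        return (self.data[self.arm_col] == arm).to_numpy()

    def covariate_matrix(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        names = list(names) if names is not None else [s.name for s in self.spec]
        return self.data[names].to_numpy(dtype=float)

    @property
    def outcomes(self) -> np.ndarray:
        return self.data[self.outcome_col].to_numpy(dtype=float)

    def spec_by_name(self, name: str) -> CovariateSpec:
        for s in self.spec:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass(frozen=True)
class AggregateTrial:
    """Published aggregate data for the AC trial.

    Covariate summaries are trial-level (pooled across arms), matching
    what publications report.
    """

    trial_id: str
    arm_summaries: Mapping[str, ArmSummary]
    covariate_summaries: Sequence[CovariateSummary]
    outcome_type: str = "continuous"

    def covariate(self, name: str) -> CovariateSummary:
        for c in self.covariate_summaries:
            if c.name == name:
                return c
        raise KeyError(f"trial {self.trial_id}: no summary for covariate {name!r}")

    @property
    def arms(self) -> list:
        return sorted(self.arm_summaries)


@dataclass(frozen=True)
class TargetPopulation:
    """An explicitly stated target population for the comparison.

    ``baseline_A`` (the absolute outcome on the common comparator in
    this population, e.g. from a registry) is required before absolute
    effects can be produced.
    """

    label: str
    covariate_summaries: Sequence[CovariateSummary] = ()
    baseline_A: Optional[ArmSummary] = None

    def covariate(self, name: str) -> CovariateSummary:
        for c in self.covariate_summaries:
            if c.name == name:
                return c
        raise KeyError(f"population {self.label}: no summary for {name!r}")


# ---------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------

def load_ipd(
    path,
    spec: Sequence[CovariateSpec],
    mapping: Optional[Mapping[str, str]] = None,
    trial_id: str = "AB",
    outcome_type: str = "continuous",
    expected_arms: Optional[Sequence[str]] = None,
) -> IPDTrial:
    """Read patient-level data from a delimited text file.

    ``mapping`` translates file column names to the canonical names
    (``arm``, ``outcome`` and the covariate names in ``spec``).  Rows
    with any missing mapped value are dropped complete-case, with the
    count logged.
    """
    df = pd.read_csv(path)
    if mapping:
        inverse = {v: k for k, v in mapping.items()}
        df = df.rename(columns=inverse)
    needed = ["arm", "outcome"] + [s.name for s in spec]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[needed]
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.warning("%s: %d row(s) dropped (missing values)", path, n0 - len(df))
    if expected_arms is not None:
        bad = set(df["arm"].unique()) - set(expected_arms)
        if bad:
            raise ValueError(f"{path}: unknown arm label(s) {sorted(bad)}")
    return IPDTrial(
        trial_id=trial_id,
        data=df.reset_index(drop=True),
        spec=list(spec),
        outcome_type=outcome_type,
    )


def _arm_summary_from_config(arm: str, cfg: Mapping, outcome_type: str) -> ArmSummary:
    n = cfg["n"]
    if outcome_type == "binary":
        if "r" in cfg:
            r = cfg["r"]
            if round(r) != r or not 0 <= r <= n:
                raise ValueError(f"arm {arm}: event count r={r} invalid for n={n}")
            ybar = r / n
        else:
            ybar = cfg["ybar"]
            r = round(ybar * n)
            if abs(r - ybar * n) > 0.5 + 1e-9:  # pragma: no cover
                raise ValueError(f"arm {arm}: proportion inconsistent with n")
        if not 0 <= ybar <= 1:
            raise ValueError(f"arm {arm}: proportion {ybar} outside [0, 1]")
        se = cfg.get("se", float(np.sqrt(max(ybar * (1 - ybar), 0.0) / n)))
        logger.debug("arm %s: derived se(ybar)=%.4g", arm, se)
    else:
        ybar = cfg["ybar"]
        if "se" in cfg:
            se = cfg["se"]
        elif "sd" in cfg:
            se = cfg["sd"] / np.sqrt(n)
        else:
            raise ValueError(f"arm {arm}: continuous outcome needs se or sd")
    return ArmSummary(arm=arm, n=n, ybar=float(ybar), se_ybar=float(se))


def load_aggregate(
    config,
    spec: Optional[Sequence[CovariateSpec]] = None,
) -> AggregateTrial:
    """Build an :class:`AggregateTrial` from a config mapping or YAML path.

    Expected schema::

        trial_id: AC
        outcome_type: binary
        arms:
          A: {n: 100, r: 30}
          C: {n: 100, r: 50}
        covariates:
          age: {mean: 60, sd: 8}
          female: {mean: 0.45}
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outcome_type = config.get("outcome_type", "continuous")
    arms = {
        arm: _arm_summary_from_config(arm, c, outcome_type)
        for arm, c in config["arms"].items()
    }
    summaries = []
    for name, c in config.get("covariates", {}).items():
        summaries.append(CovariateSummary(name=name, mean=c["mean"], sd=c.get("sd")))
    if spec is not None:
        known = {s.name for s in spec}
        unknown = [c.name for c in summaries if c.name not in known]
        if unknown:
            raise ValueError(f"covariate summaries not in spec: {unknown}")
        for s in spec:
            if s.match_moments == "mean_and_variance":
                cs = next((c for c in summaries if c.name == s.name), None)
                if cs is not None and cs.sd is None:
                    raise ValueError(
                        f"{s.name}: variance matching requested but no sd supplied"
                    )
    return AggregateTrial(
        trial_id=config.get("trial_id", "AC"),
        arm_summaries=arms,
        covariate_summaries=summaries,
        outcome_type=outcome_type,
    )


def load_target_population(config) -> TargetPopulation:
    """Build a :class:`TargetPopulation` from a config mapping or YAML path."""
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    baseline = None
    if "baseline_A" in config:
        b = config["baseline_A"]
        baseline = ArmSummary(
            arm="A", n=b.get("n", 1), ybar=b["ybar"], se_ybar=b.get("se")
        )
    summaries = [
        CovariateSummary(name=name, mean=c["mean"], sd=c.get("sd"))
        for name, c in config.get("covariates", {}).items()
    ]
    return TargetPopulation(
        label=config.get("label", "target"),
        covariate_summaries=summaries,
        baseline_A=baseline,
    )


# ---------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------

def summarize_ipd(trial: IPDTrial):
    """Trial-level covariate summaries and per-arm outcome summaries.

    Covariate means/SDs are pooled across arms (sample SD, denominator
    n-1), mirroring what aggregate publications report.
    """
    cov = []
    for s in trial.spec:
        x = trial.data[s.name].to_numpy(dtype=float)
        if s.kind == "binary":
            cov.append(CovariateSummary(name=s.name, mean=float(x.mean())))
        else:
            cov.append(
                CovariateSummary(
                    name=s.name, mean=float(x.mean()), sd=float(x.std(ddof=1))
                )
            )
    arms = {}
    for arm in trial.arms:
        mask = trial.arm_mask(arm)
        y = trial.outcomes[mask]
        n = int(mask.sum())
        if trial.outcome_type == "binary":
            ybar = float(y.mean())
            se = float(np.sqrt(max(ybar * (1 - ybar), 0.0) / n))
        else:
            ybar = float(y.mean())
            se = float(y.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        arms[arm] = ArmSummary(arm=arm, n=n, ybar=ybar, se_ybar=se)
    return cov, arms
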