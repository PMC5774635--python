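import numpy as np
import pandas as pd
import pytest

from popadjust import CovariateSpec, CovariateSummary, IPDTrial


@pytest.fixture
def toy_binary_trial():
    """Four patients, one binary covariate: the closed-form weighting case."""
    df = pd.DataFrame(
        {
            "arm": ["A", "A", "B", "B"],
            "outcome": [0, 0, 1, 1],
            "x": [0, 0, 1, 1],
        }
    )
    spec = [CovariateSpec("x", kind="binary", role="effect_modifier")]
    return IPDTrial("AB", df, spec, outcome_type="binary")


def make_random_trial(rng, n=200, outcome="continuous"):
    """Mixed binary/continuous covariates with a variance-matched one."""
    x1 = rng.normal(0.0, 1.0, n)
    x2 = rng.binomial(1, 0.5, n).astype(float)
    x3 = rng.normal(2.0, 1.5, n)
    y = rng.normal(0, 1, n) if outcome == "continuous" else rng.binomial(1, 0.5, n)
    df = pd.DataFrame(
        {
            "arm": ["A"] * (n // 2) + ["B"] * (n - n // 2),
            "outcome": y.astype(float),
            "x1": x1,
            "x2": x2,
            "x3": x3,
        }
    )
    spec = [
        CovariateSpec("x1", role="effect_modifier", match_moments="mean_and_variance"),
        CovariateSpec("x2", kind="binary", role="both"),
        CovariateSpec("x3", role="effect_modifier"),
    ]
    return IPDTrial("AB", df, spec, outcome_type=outcome)


def random_targets(rng, trial):
    """Targets drawn safely inside the observed covariate support."""
    out = []
    for s in trial.spec:
        x = trial.data[s.name].to_numpy()
        if s.kind == "binary":
            out.append(CovariateSummary(s.name, float(rng.uniform(0.3, 0.7))))
        else:
            lo, hi = np.quantile(x, [0.25, 0.75])
            mean = float(rng.uniform(lo, hi))
            sd = float(x.std(ddof=1) * rng.uniform(0.7, 1.0))
            out.append(CovariateSummary(s.name, mean, sd))
    return out
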