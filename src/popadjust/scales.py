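"""Link-scale machinery for indirect comparisons.

Relative treatment effects are assumed additive on a *linear predictor*
scale reached through a link function ``g``: the identity (mean
differences / risk differences), the log (risk ratios), or the logit
(odds ratios).  Every downstream estimator carries the scale it was
formed on so that effects are never mixed across scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Scale", "get_scale", "IDENTITY", "LOG", "LOGIT"]


class ScaleDomainError(ValueError):
    """Outcome value outside the domain of the requested link."""


@dataclass(frozen=True)
class Scale:
    """A link scale: the transform ``g``, its inverse and derivative.

    Parameters
    ----------
    name : str
        One of ``identity``, ``log``, ``logit``.
    g : callable
        Natural-outcome -> linear-predictor transform.
    g_inv : callable
        Inverse transform.
    dg : callable
        Derivative of ``g`` (used in delta-method standard errors).
    domain_check : callable
        Returns a boolean array marking in-domain values.
    """

    name: str
    g: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    g_inv: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    dg: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    domain_check: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def link(self, y):
        """Apply ``g`` after validating the domain."""
        y = np.asarray(y, dtype=float)
        ok = self.domain_check(y)
        if not np.all(ok):
            bad = np.atleast_1d(y)[~np.atleast_1d(ok)][0]
            raise ScaleDomainError(
                f"value {bad!r} outside the domain of the {self.name} link"
            )
        return self.g(y)

    def link_inv(self, eta):
        return self.g_inv(np.asarray(eta, dtype=float))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _expit(eta):
    return 1.0 / (1.0 + np.exp(-eta))


IDENTITY = Scale(
    name="identity",
    g=lambda y: y,
    g_inv=lambda eta: eta,
    dg=lambda y: np.ones_like(np.asarray(y, dtype=float)),
    domain_check=lambda y: np.isfinite(y),
)

LOG = Scale(
    name="log",
    g=np.log,
    g_inv=np.exp,
    dg=lambda y: 1.0 / y,
    domain_check=lambda y: np.isfinite(y) & (y > 0),
)

LOGIT = Scale(
    name="logit",
    g=lambda y: np.log(y / (1.0 - y)),
    g_inv=_expit,
    dg=lambda y: 1.0 / (y * (1.0 - y)),
    domain_check=lambda y: np.isfinite(y) & (y > 0) & (y < 1),
)

_REGISTRY = {s.name: s for s in (IDENTITY, LOG, LOGIT)}


def get_scale(name: "str | Scale") -> Scale:
    """Resolve a scale by name (``identity``, ``log``, ``logit``)."""
    if isinstance(name, Scale):
        return name
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown scale {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None


def link(scale, y):
    """Functional form of :meth:`Scale.link`."""
    return get_scale(scale).link(y)


def link_inv(scale, eta):
    """Functional form of :meth:`Scale.link_inv`."""
    return get_scale(scale).link_inv(eta)
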