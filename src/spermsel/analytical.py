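"""Closed-form model of relative fertilization success under full mate sampling.

When every female samples every male, the loaded raffle has an analytical
limit. With storage-organ sizes x ~ N(0, sigma_F^2) (density F), sperm sizes
y ~ N(0, sigma_M^2) (density M) and the Gaussian preference
U(x, y) = exp(-(x - y)^2 / (2 sigma_U^2)):

* ``V(x) = integral M(y) U(x, y) dy`` is the total fit score a female of
  size x assigns to the male population,
* ``S(y | x) = M(y) U(x, y) / V(x)`` is the fertilization-success density a
  single female of size x confers,
* ``S(y) = integral F(x) S(y | x) dx = M(y) R(y)`` averages over females,
* ``R(y) = S(y) / M(y)`` is fertilization success relative to a male's
  representation in the population, normalized so that
  ``integral M(y) R(y) dy = 1``.

Closed forms (verified against adaptive quadrature of the defining
integrals):

    V(x) = sigma_U / sqrt(sigma_M^2 + sigma_U^2)
           * exp(-x^2 / (2 (sigma_M^2 + sigma_U^2)))
    R(y) = (sigma_M^2 + sigma_U^2) / sqrt(K)
           * exp(-y^2 (sigma_M^2 + sigma_U^2 - sigma_F^2) / (2 K)),
    K    = sigma_F^2 sigma_M^2 + sigma_M^2 sigma_U^2 + sigma_U^4.

The sign of d = sigma_F^2 - (sigma_M^2 + sigma_U^2) decides the regime:
R is bell-shaped with R(0) > 1 (stabilizing selection on sperm size) when
d < 0, constant 1 (no selection) when d = 0, and U-shaped with R(0) < 1
(disruptive selection) when d > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .engine import preference_weight

__all__ = [
    "AnalyticalParams",
    "storage_density",
    "sperm_density",
    "total_fit",
    "conditional_success",
    "relative_success",
    "success_density",
    "classify_regime",
    "numerical_total_fit",
    "numerical_relative_success",
    "mean_relative_success",
    "regime_map",
]

REGIME_STABILIZING = "stabilizing"
REGIME_NONE = "none"
REGIME_DISRUPTIVE = "disruptive"


@dataclass(frozen=True)
class AnalyticalParams:
    """The three SDs of the model plus the tolerance for the knife-edge regime.

    ``none_tol`` bounds |sigma_F^2 - sigma_M^2 - sigma_U^2| below which the
    regime is called "none" (exact equality is measure-zero in floats).
    """

    sigma_F: float
    sigma_M: float = 1.0
    sigma_U: float = 1.0
    none_tol: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("sigma_F", "sigma_M", "sigma_U"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a strictly positive real, got {v!r}")
        if self.none_tol < 0:
            raise ValueError("none_tol must be non-negative")

    @property
    def K(self) -> float:
        """sigma_F^2 sigma_M^2 + sigma_M^2 sigma_U^2 + sigma_U^4 (always > 0)."""
        sf2, sm2, su2 = self.sigma_F**2, self.sigma_M**2, self.sigma_U**2
        return sf2 * sm2 + sm2 * su2 + su2 * su2

    @property
    def discriminant(self) -> float:
        """d = sigma_F^2 - (sigma_M^2 + sigma_U^2); its sign sets the regime."""
        return self.sigma_F**2 - (self.sigma_M**2 + self.sigma_U**2)

    @property
    def regime(self) -> str:
        return classify_regime(self)


def storage_density(x, params: AnalyticalParams):
    """F(x): normal density of storage-organ size across females."""
    return stats.norm.pdf(x, loc=0.0, scale=params.sigma_F)


def sperm_density(y, params: AnalyticalParams):
    """M(y): normal density of sperm size across males."""
    return stats.norm.pdf(y, loc=0.0, scale=params.sigma_M)


def total_fit(x, params: AnalyticalParams):
    """V(x): total fit score of the male population for a female of size x."""
    s2 = params.sigma_M**2 + params.sigma_U**2
    x = np.asarray(x, dtype=float)
    return params.sigma_U / math.sqrt(s2) * np.exp(-(x * x) / (2.0 * s2))


def conditional_success(y, x, params: AnalyticalParams):
    """S(y | x): success density conferred by a single female of size x."""
    num = sperm_density(y, params) * preference_weight(x, y, params.sigma_U)
    return num / total_fit(x, params)


def relative_success(y, params: AnalyticalParams):
    """R(y): closed-form fertilization success relative to representation."""
    s2 = params.sigma_M**2 + params.sigma_U**2
    K = params.K
    y = np.asarray(y, dtype=float)
    return s2 / math.sqrt(K) * np.exp(-(y * y) * (s2 - params.sigma_F**2) / (2.0 * K))


def success_density(y, params: AnalyticalParams):
    """S(y) = M(y) R(y): unconditional fertilization-success density."""
    return sperm_density(y, params) * relative_success(y, params)


def classify_regime(params: AnalyticalParams) -> str:
    """Stabilizing / none / disruptive by the sign of the discriminant."""
    d = params.discriminant
    if abs(d) <= params.none_tol:
        return REGIME_NONE
    return REGIME_STABILIZING if d < 0 else REGIME_DISRUPTIVE


def _quad(fun, lo, hi, tag: str, epsabs: float, epsrel: float) -> float:
    value, abserr, info, *rest = integrate.quad(
        fun, lo, hi, epsabs=epsabs, epsrel=epsrel, limit=400, full_output=True
    )
    if rest:  # a warning message means the quadrature did not converge
        raise RuntimeError(f"quadrature for {tag} did not converge: {rest[0]}")
    return value


def numerical_total_fit(
    x: float,
    params: AnalyticalParams,
    n_sd: float = 10.0,
    epsabs: float = 1e-13,
    epsrel: float = 1e-13,
) -> float:
    """V(x) by adaptive quadrature of its defining integral over y."""
    span = n_sd * max(params.sigma_M, params.sigma_U)
    lo, hi = min(-span, x - span), max(span, x + span)
    return _quad(
        lambda y: sperm_density(y, params) * preference_weight(x, y, params.sigma_U),
        lo,
        hi,
        f"V({x})",
        epsabs,
        epsrel,
    )


def numerical_relative_success(
    y: float,
    params: AnalyticalParams,
    n_sd: float = 10.0,
    epsabs: float = 1e-12,
    epsrel: float = 1e-12,
    closed_form_inner: bool = False,
) -> float:
    """R(y) by adaptive quadrature of its defining integral over x.

    By default the inner total-fit normalizer V(x) is itself computed by
    quadrature, keeping this estimate fully independent of the closed form
    it is used to check; ``closed_form_inner=True`` trades that independence
    for speed.
    """
    if closed_form_inner:
        inner = lambda x: float(total_fit(x, params))  # noqa: E731
    else:
        inner = lambda x: numerical_total_fit(x, params, n_sd=n_sd)  # noqa: E731
    span = n_sd * max(params.sigma_F, params.sigma_M, params.sigma_U)
    lo, hi = min(-span, y - span), max(span, y + span)
    return _quad(
        lambda x: storage_density(x, params)
        * preference_weight(x, y, params.sigma_U)
        / inner(x),
        lo,
        hi,
        f"R({y})",
        epsabs,
        epsrel,
    )


def mean_relative_success(
    params: AnalyticalParams,
    use_numerical: bool = False,
    n_sd: float = 10.0,
) -> float:
    """integral M(y) R(y) dy — equals 1 for every valid parameter set."""
    if use_numerical:
        r = lambda y: numerical_relative_success(  # noqa: E731
            y, params, n_sd=n_sd, closed_form_inner=True
        )
        eps = 1e-9
    else:
        r = lambda y: float(relative_success(y, params))  # noqa: E731
        eps = 1e-12
    span = n_sd * max(params.sigma_F, params.sigma_M, params.sigma_U)
    return _quad(
        lambda y: sperm_density(y, params) * r(y), -span, span, "mean R", eps, eps
    )


def regime_map(
    sigma_F_values,
    sigma_U_values,
    sigma_M: float = 1.0,
    none_tol: float = 1e-12,
) -> pd.DataFrame:
    """Regime label over a (sigma_F, sigma_U) grid at fixed sigma_M."""
    rows = []
    for sf in sigma_F_values:
        for su in sigma_U_values:
            p = AnalyticalParams(
                sigma_F=float(sf), sigma_M=sigma_M, sigma_U=float(su), none_tol=none_tol
            )
            rows.append((p.sigma_F, p.sigma_U, p.discriminant, p.regime))
    return pd.DataFrame(
        rows, columns=["sigma_F", "sigma_U", "discriminant", "regime"]
    )
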