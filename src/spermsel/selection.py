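"""Lande–Arnold selection-gradient estimation for one replicate population.

Reproductive success is divided by its population mean (relative fitness
``w``), sperm size is standardized to realized sample mean 0 and sample SD 1
(``z``, n-1 denominator), and ``w`` is regressed on ``z`` and ``z^2`` by
ordinary least squares. The coefficient on ``z`` is the linear gradient
(beta); the raw coefficient on ``z^2`` is reported as the quadratic gradient
(gamma) with no doubling — negative gamma indicates stabilizing selection,
positive gamma disruptive selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import ReplicateResult

__all__ = [
    "GradientRecord",
    "relative_fitness",
    "standardize_trait",
    "quadratic_gradient",
    "replicate_gradient",
]


@dataclass(frozen=True)
class GradientRecord:
    """Per-replicate selection-gradient estimates plus condition labels."""

    beta_linear: float
    gamma_quadratic: float
    sigma_F: Optional[float] = None
    n_partners: Optional[int] = None
    replicate: Optional[int] = None


def relative_fitness(offspring_count) -> np.ndarray:
    """Offspring counts divided by their mean; output mean is exactly 1."""
    counts = np.asarray(offspring_count, dtype=float)
    if counts.size == 0:
        raise ValueError("offspring_count is empty")
    if (counts < 0).any():
        raise ValueError("offspring counts must be non-negative")
    mean = counts.mean()
    if mean <= 0:
        raise ValueError("mean reproductive success is zero; cannot standardize")
    return counts / mean


def standardize_trait(values) -> np.ndarray:
    """Center and scale to sample mean 0 and sample SD 1 (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to standardize")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("trait has zero variance; cannot standardize")
    return (v - v.mean()) / sd


def quadratic_gradient(w, z, **labels) -> GradientRecord:
    """OLS of relative fitness on standardized trait and its square.

    With constant fitness there is no selection and both gradients are
    returned as exact zeros (the regression would only add float residue).
    Keyword arguments become condition labels on the record.
    """
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    if w.shape != z.shape or w.ndim != 1:
        raise ValueError("w and z must be 1-D arrays of equal length")
    if w.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(z).size < 3:
        raise ValueError("design is collinear: fewer than 3 distinct trait values")
    if np.ptp(w) == 0.0:
        return GradientRecord(beta_linear=0.0, gamma_quadratic=0.0, **labels)
    design = np.column_stack([np.ones_like(z), z, z * z])
    coef, _, rank, _ = np.linalg.lstsq(design, w, rcond=None)
    if rank < 3:
        raise ValueError("design is rank-deficient")
    return GradientRecord(
        beta_linear=float(coef[1]), gamma_quadratic=float(coef[2]), **labels
    )


def replicate_gradient(result: ReplicateResult, **labels) -> GradientRecord:
    """Gradient record for one finished engine replicate."""
    w = relative_fitness(result.fertilization.offspring_count)
    z = standardize_trait(result.population.male_trait)
    return quadratic_gradient(w, z, **labels)
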