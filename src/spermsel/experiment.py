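"""The factorial experiment: sigma_F levels x promiscuity levels x replicates.

`run_grid` simulates every cell of the factorial design, estimating the
quadratic selection gradient in each replicate population. The resulting
:class:`ExperimentResult` summarizes each condition by the median and
empirical 95% quantile limits of gamma, and quantifies the two factors and
their interaction with classical eta-squared (SS_effect / SS_total) from a
balanced two-way fixed-effects ANOVA treating both predictors as
categorical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .config import SimulationConfig
from .engine import run_replicate
from .selection import replicate_gradient

__all__ = [
    "ExperimentResult",
    "run_grid",
    "eta_squared",
    "quantile_summary",
    "replicate_rng",
    "PAPER_SIGMA_F_LEVELS",
    "PAPER_PARTNER_LEVELS",
    "PAPER_REPLICATES",
]

# the published factorial design
PAPER_SIGMA_F_LEVELS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
PAPER_PARTNER_LEVELS: tuple[int, ...] = (1, 2, 3, 5, 10)
PAPER_REPLICATES: int = 1000

DEFAULT_QUANTILES: tuple[float, float] = (0.025, 0.975)

GRADIENT_COLUMNS = [
    "sigma_F",
    "n_partners",
    "replicate",
    "beta_linear",
    "gamma_quadratic",
    "seed",
]


def replicate_rng(master_seed: int, cell: int, replicate: int) -> np.random.Generator:
    """The exact RNG used for one replicate of one grid cell.

    Sub-streams are spawned as ``SeedSequence(master_seed, spawn_key=(cell,
    replicate))``, so any replicate is reproducible in isolation from the
    master seed and its grid coordinates, and replicate-level parallelism
    cannot change results.
    """
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(cell, replicate))
    )


@dataclass
class ExperimentResult:
    """Replicate-level gradients for a full factorial grid, plus summaries."""

    gradients: pd.DataFrame
    master_seed: int
    quantile_probs: tuple[float, float] = DEFAULT_QUANTILES
    base_config: SimulationConfig | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        """Per-condition median and quantile limits of gamma."""
        return quantile_summary(self.gradients, self.quantile_probs)

    def eta_squared(self, include_residual: bool = False) -> pd.Series:
        """Classical eta-squared of the two factors and their interaction."""
        return eta_squared(self.gradients, include_residual=include_residual)


def run_grid(
    base_config: SimulationConfig,
    sigma_F_levels: Sequence[float],
    partner_levels: Sequence[int],
    n_replicates: int,
    master_seed: int,
    quantile_probs: tuple[float, float] = DEFAULT_QUANTILES,
) -> ExperimentResult:
    """Simulate every cell of the factorial design.

    Each of the ``len(sigma_F_levels) * len(partner_levels)`` cells receives
    ``n_replicates`` independent replicate populations; per-replicate RNG
    sub-streams all derive from ``master_seed`` (see :func:`replicate_rng`),
    so the gradients table is bitwise-reproducible.
    """
    if not sigma_F_levels or not partner_levels:
        raise ValueError("factor levels must be non-empty")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per cell")
    records = []
    cells = list(itertools.product(sigma_F_levels, partner_levels))
    for cell_idx, (sf, k) in enumerate(cells):
        try:
            cfg = base_config.replace(sigma_F=float(sf), n_partners=int(k))
        except ValueError as err:
            raise ValueError(
                f"invalid grid cell sigma_F={sf}, n_partners={k}: {err}"
            ) from err
        for rep in range(n_replicates):
            rng = replicate_rng(master_seed, cell_idx, rep)
            try:
                rec = replicate_gradient(
                    run_replicate(cfg, rng),
                    sigma_F=float(sf),
                    n_partners=int(k),
                    replicate=rep,
                )
            except Exception as err:
                raise RuntimeError(
                    f"replicate {rep} of cell sigma_F={sf}, n_partners={k} "
                    f"failed: {err}"
                ) from err
            records.append(
                (
                    rec.sigma_F,
                    rec.n_partners,
                    rec.replicate,
                    rec.beta_linear,
                    rec.gamma_quadratic,
                    f"{master_seed}:{cell_idx}:{rep}",
                )
            )
    gradients = pd.DataFrame.from_records(records, columns=GRADIENT_COLUMNS)
    return ExperimentResult(
        gradients=gradients,
        master_seed=master_seed,
        quantile_probs=quantile_probs,
        base_config=base_config,
    )


def _check_balanced(gradients: pd.DataFrame) -> None:
    counts = gradients.groupby(["sigma_F", "n_partners"]).size()
    expected_cells = gradients["sigma_F"].nunique() * gradients["n_partners"].nunique()
    if len(counts) != expected_cells or counts.nunique() != 1:
        raise ValueError(
            "eta-squared requires a balanced complete factorial layout; "
            f"got cell sizes {sorted(counts.unique())} over {len(counts)} cells"
        )


def eta_squared(gradients: pd.DataFrame, include_residual: bool = False) -> pd.Series:
    """Classical eta-squared (SS_effect / SS_total) for the two-way ANOVA.

    Both predictors are treated as categorical; the design must be a
    balanced complete factorial, where sequential and marginal sums of
    squares coincide. The three effect shares plus the residual share sum
    to 1.
    """
    _check_balanced(gradients)
    model = smf.ols(
        "gamma_quadratic ~ C(sigma_F) * C(n_partners)", data=gradients
    ).fit()
    table = anova_lm(model, typ=2)
    ss = table["sum_sq"]
    total = ss.sum()
    if total == 0:
        raise ValueError("zero total sum of squares; response is constant")
    out = pd.Series(
        {
            "sigma_F": ss["C(sigma_F)"] / total,
            "n_partners": ss["C(n_partners)"] / total,
            "interaction": ss["C(sigma_F):C(n_partners)"] / total,
        },
        name="eta_squared",
    )
    if include_residual:
        out["residual"] = ss["Residual"] / total
    return out


def quantile_summary(
    gradients: pd.DataFrame,
    probs: tuple[float, float] = DEFAULT_QUANTILES,
) -> pd.DataFrame:
    """Median and empirical quantile limits of gamma per condition.

    Quantiles use linear interpolation of order statistics. One row per
    (sigma_F, n_partners) condition, columns ``median``, ``lower``,
    ``upper`` and ``n``.
    """
    lo, hi = probs
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"quantile probabilities must satisfy 0 <= lo < hi <= 1, got {probs}")
    grouped = gradients.groupby(["sigma_F", "n_partners"])["gamma_quadratic"]
    out = grouped.agg(
        median="median",
        lower=lambda g: g.quantile(lo),
        upper=lambda g: g.quantile(hi),
        n="size",
    ).reset_index()
    return out
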