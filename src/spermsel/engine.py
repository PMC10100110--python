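"""One breeding season: trait draws, mating assignment, loaded-raffle fertilization.

The model is built around cryptic female choice by morphological fit: each
female's sperm-storage-organ size ``x`` defines her most-preferred sperm
size, and a male with sperm size ``y`` receives the Gaussian fit score
``exp(-(x - y)^2 / (2 sigma_U^2))``. After every individual has copulated
with its assigned partners, each egg is fertilized by one of the female's
partners drawn with probability proportional to his fit score (a loaded
raffle), so success is relative to the other partners, never absolute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig

__all__ = [
    "Population",
    "MatingAssignment",
    "FertilizationResult",
    "ReplicateResult",
    "RetryBudgetError",
    "preference_weight",
    "draw_population",
    "assign_matings",
    "fertilize",
    "run_replicate",
]

#: Per-round cap on whole-round permutation redraws. At the largest condition
#: considered here (200 x 200, 10 partners) the expected number of redraws in
#: the final round is ~e^9 ~ 8e3, so the cap is far out in the tail while
#: still catching genuinely infeasible configurations.
DEFAULT_MAX_RETRIES = 200_000


class RetryBudgetError(RuntimeError):
    """The rejection sampler for one copulation round ran out of redraws."""


@dataclass(frozen=True)
class Population:
    """Realized trait values for one replicate population."""

    male_trait: np.ndarray  # sperm size y, one per male
    female_trait: np.ndarray  # storage-organ size x, one per female


@dataclass(frozen=True)
class MatingAssignment:
    """Copulation partners: one row per female, one column per round.

    Entries are male indices; within each row all entries are distinct
    (no male copulates twice with the same female).
    """

    partners: np.ndarray


@dataclass(frozen=True)
class FertilizationResult:
    """Sires per egg and resulting per-male offspring counts."""

    sire: np.ndarray  # male index, one row per female, one column per egg
    offspring_count: np.ndarray  # length n_males


@dataclass(frozen=True)
class ReplicateResult:
    """Everything one replicate produced."""

    population: Population
    matings: MatingAssignment
    fertilization: FertilizationResult


def preference_weight(x, y, sigma_U: float = 1.0):
    """Gaussian fit score between storage-organ size ``x`` and sperm size ``y``.

    Returns ``exp(-(x - y)^2 / (2 sigma_U^2))``, in ``(0, 1]`` with the
    maximum 1 attained exactly when ``x == y``. Broadcasts over array input.
    """
    if not sigma_U > 0:
        raise ValueError(f"sigma_U must be > 0, got {sigma_U!r}")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return np.exp(-(d * d) / (2.0 * sigma_U * sigma_U))


def draw_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Draw i.i.d. normal sperm sizes and storage-organ sizes.

    Males ~ Normal(mu_M, sigma_M^2), females ~ Normal(mu_F, sigma_F^2);
    draws are never clipped.
    """
    male = rng.normal(config.mu_M, config.sigma_M, size=config.n_males)
    female = rng.normal(config.mu_F, config.sigma_F, size=config.n_females)
    return Population(male_trait=male, female_trait=female)


def _batch_permutations(n_perms: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n_perms`` independent uniform permutations of ``range(n)``, stacked.

    Ranking i.i.d. uniforms row-wise is a uniform permutation (ties have
    probability zero) and is faster than per-row shuffles at these sizes.
    """
    return np.argsort(rng.random((n_perms, n)), axis=1)


def _assign_symmetric(
    n: int, k: int, rng: np.random.Generator, max_retries: int
) -> np.ndarray:
    """k rounds of random perfect matchings with no repeated pair.

    Each round pairs the n females with the n males by a uniform random
    permutation; if any female would receive a male she already has, the
    entire round is redrawn. Redraws are generated in growing batches, which
    leaves the distribution unchanged (a uniform permutation conditioned on
    avoiding all previous pairs) but keeps the high-promiscuity conditions
    fast.
    """
    partners = np.empty((n, k), dtype=np.intp)
    partners[:, 0] = rng.permutation(n)
    if k == 1:
        return partners
    rows = np.arange(n)
    taken = np.zeros((n, n), dtype=bool)
    taken[rows, partners[:, 0]] = True
    for r in range(1, k):
        tries = 0
        batch = 16
        chosen = None
        while chosen is None:
            if tries >= max_retries:
                raise RetryBudgetError(
                    f"round {r + 1}: no duplicate-free permutation found in "
                    f"{max_retries} redraws (n={n}, partners={k})"
                )
            b = min(batch, max_retries - tries)
            perms = _batch_permutations(b, n, rng)
            ok = ~taken[rows, perms].any(axis=1)
            hits = np.flatnonzero(ok)
            if hits.size:
                chosen = perms[hits[0]]
            tries += b
            batch = min(batch * 4, 8192)
        partners[:, r] = chosen
        taken[rows, chosen] = True
    return partners


def _assign_stub(
    config: SimulationConfig, rng: np.random.Generator, max_retries: int
) -> np.ndarray:
    """Asymmetric promiscuity: shuffle male copulation stubs, deal per female.

    Every male contributes exactly ``partners_per_male`` stubs; the shuffled
    stub list is dealt ``partners_per_female`` per female, and the whole deal
    is redrawn if any female holds the same male twice.
    """
    pf, pm = config.partners_per_female, config.partners_per_male
    stubs = np.repeat(np.arange(config.n_males), pm)
    for _ in range(max_retries):
        dealt = rng.permutation(stubs).reshape(config.n_females, pf)
        row_sorted = np.sort(dealt, axis=1)
        if not (row_sorted[:, 1:] == row_sorted[:, :-1]).any():
            return dealt
    raise RetryBudgetError(
        f"no duplicate-free stub deal found in {max_retries} redraws "
        f"(n_females={config.n_females}, partners_per_female={pf})"
    )


def assign_matings(
    config: SimulationConfig,
    rng: np.random.Generator,
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> MatingAssignment:
    """Assign copulation partners for every female.

    Default (symmetric) scheme: ``n_partners`` rounds, each a uniform random
    permutation pairing females to males, the whole round redrawn whenever a
    pair would repeat. Every female ends up with ``n_partners`` distinct
    males and every male with ``n_partners`` distinct females. The
    asymmetric variant (``n_partners_female`` != ``n_partners_male``)
    instead deals shuffled male copulation stubs.
    """
    if config.is_symmetric:
        table = _assign_symmetric(config.n_females, config.n_partners, rng, max_retries)
    else:
        table = _assign_stub(config, rng, max_retries)
    return MatingAssignment(partners=table)


def fertilize(
    pop: Population,
    assignment: MatingAssignment,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> FertilizationResult:
    """Resolve every egg by a loaded raffle among the female's partners.

    For each female the preference weights of her partners are computed and
    each of her eggs independently draws a sire with probability
    proportional to his weight (draws with replacement across eggs). With
    ``winner_take_all`` a single weighted draw sires the whole clutch. With
    ``storage_threshold`` set, partners whose weight falls below the cutoff
    are excluded from the raffle; if a female has no stored sperm at all her
    eggs are still fertilized, by a uniform raffle among her partners.
    """
    partners = assignment.partners
    n_f, k = partners.shape
    weights = preference_weight(
        pop.female_trait[:, None], pop.male_trait[partners], config.sigma_U
    )
    if config.storage_threshold is not None:
        weights = np.where(weights >= config.storage_threshold, weights, 0.0)
    totals = weights.sum(axis=1)
    empty = totals <= 0.0
    if empty.any():
        if config.storage_threshold is None:
            # true floating-point underflow of every weight in a row
            warnings.warn(
                f"preference weights underflowed to 0 for {int(empty.sum())} "
                "female(s); falling back to a uniform raffle among partners",
                RuntimeWarning,
                stacklevel=2,
            )
        weights = np.where(empty[:, None], 1.0, weights)
        totals = weights.sum(axis=1)

    n_draws = 1 if config.winner_take_all else config.eggs_per_female
    cum = np.cumsum(weights, axis=1)
    u = rng.random((n_f, n_draws)) * totals[:, None]
    # index of the first cumulative bin exceeding u; zero-width (excluded)
    # bins can never be selected
    idx = (u[:, :, None] >= cum[:, None, :]).sum(axis=2)
    sire = partners[np.arange(n_f)[:, None], idx]
    if config.winner_take_all:
        sire = np.repeat(sire, config.eggs_per_female, axis=1)
    counts = np.bincount(sire.ravel(), minlength=config.n_males)
    return FertilizationResult(sire=sire, offspring_count=counts)


def run_replicate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ReplicateResult:
    """Run one full breeding season under ``config``.

    When ``rng`` is omitted a fresh generator is seeded from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = draw_population(config, rng)
    matings = assign_matings(config, rng)
    fert = fertilize(pop, matings, config, rng)
    return ReplicateResult(population=pop, matings=matings, fertilization=fert)
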