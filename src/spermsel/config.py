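"""Configuration for one simulation condition.

A :class:`SimulationConfig` pins down everything a single breeding-season
replicate needs: population sizes, the three standard deviations of the
model (``sigma_F`` for female sperm-storage-organ size, ``sigma_M`` for male
sperm size, ``sigma_U`` for the width of the Gaussian preference function),
promiscuity (number of distinct copulation partners), clutch size, and the
optional model variants (winner-take-all fertilization, a storage threshold
below which sperm are not stored, and sex-asymmetric promiscuity).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

__all__ = ["SimulationConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulation condition.

    Parameters
    ----------
    sigma_F
        Among-female SD of sperm-storage-organ size (the "preference
        variation"). Must be > 0.
    n_partners
        Number of distinct copulation partners per individual. Under the
        default symmetric mating scheme every female copulates with
        ``n_partners`` distinct males and every male with ``n_partners``
        distinct females.
    n_females, n_males
        Population sizes (default 200 each).
    eggs_per_female
        Clutch size; every egg is fertilized (default 5).
    sigma_M
        Among-male SD of sperm size (default 1).
    sigma_U
        Width parameter of the Gaussian preference function
        ``exp(-(x - y)^2 / (2 sigma_U^2))`` (default 1).
    mu_F, mu_M
        Trait means (default 0 and 0; unequal means support drift-style
        explorations).
    winner_take_all
        If set, a single weighted draw decides the sire of a female's
        entire clutch instead of one draw per egg.
    storage_threshold
        If set, partners whose preference weight falls below this cutoff
        are treated as unstored (weight zeroed) before the raffle. Must lie
        in ``[0, 1)`` since weights are in ``(0, 1]``.
    n_partners_female, n_partners_male
        Optional distinct promiscuity levels for the asymmetric variant.
        Both must be given together and must satisfy the copulation balance
        ``n_females * n_partners_female == n_males * n_partners_male``.
    seed
        Seed used when a replicate is run without an explicit RNG.
    """

    sigma_F: float
    n_partners: int
    n_females: int = 200
    n_males: int = 200
    eggs_per_female: int = 5
    sigma_M: float = 1.0
    sigma_U: float = 1.0
    mu_F: float = 0.0
    mu_M: float = 0.0
    winner_take_all: bool = False
    storage_threshold: Optional[float] = None
    n_partners_female: Optional[int] = None
    n_partners_male: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_females", "n_males", "eggs_per_female", "n_partners"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        for name in ("sigma_F", "sigma_M", "sigma_U"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be a strictly positive real, got {value!r}")
        for name in ("mu_F", "mu_M"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{name} must be a finite real, got {value!r}")
        if self.storage_threshold is not None:
            t = self.storage_threshold
            if not (isinstance(t, (int, float)) and 0.0 <= t < 1.0):
                raise ValueError(
                    f"storage_threshold must lie in [0, 1), got {t!r} "
                    "(preference weights are in (0, 1])"
                )
        if (self.n_partners_female is None) != (self.n_partners_male is None):
            raise ValueError(
                "n_partners_female and n_partners_male must be given together"
            )
        if self.n_partners_female is not None:
            for name in ("n_partners_female", "n_partners_male"):
                value = getattr(self, name)
                if not isinstance(value, int) or isinstance(value, bool) or value < 1:
                    raise ValueError(f"{name} must be a positive integer, got {value!r}")
            if self.n_females * self.n_partners_female != self.n_males * self.n_partners_male:
                raise ValueError(
                    "asymmetric promiscuity requires the copulation balance "
                    "n_females * n_partners_female == n_males * n_partners_male "
                    f"({self.n_females} * {self.n_partners_female} != "
                    f"{self.n_males} * {self.n_partners_male})"
                )
        if self.partners_per_female > self.n_males:
            raise ValueError(
                f"each female needs {self.partners_per_female} distinct male partners "
                f"but only {self.n_males} males exist"
            )
        if self.partners_per_male > self.n_females:
            raise ValueError(
                f"each male needs {self.partners_per_male} distinct female partners "
                f"but only {self.n_females} females exist"
            )
        if self.is_symmetric and self.n_females != self.n_males:
            raise ValueError(
                "the symmetric mating scheme pairs females and males by a per-round "
                "permutation and requires n_females == n_males; use "
                "n_partners_female/n_partners_male for unequal populations"
            )

    @property
    def partners_per_female(self) -> int:
        """Distinct copulation partners per female."""
        return self.n_partners_female if self.n_partners_female is not None else self.n_partners

    @property
    def partners_per_male(self) -> int:
        """Distinct copulation partners per male."""
        return self.n_partners_male if self.n_partners_male is not None else self.n_partners

    @property
    def is_symmetric(self) -> bool:
        """True when the default permutation-per-round scheme applies."""
        return self.n_partners_female is None and self.n_partners_male is None

    def replace(self, **changes) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        """Plain-dict form with None-valued optionals dropped."""
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}
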