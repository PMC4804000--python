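"""Vital-rate containers for the polar bear life cycle.

Survival is parameterized by sex and age class (cub-of-year, yearling,
subadult, adult), reproduction by the age-specific probability that an
*available* female (lone, or accompanying dispersing two-year-old cubs)
produces a litter, together with a mean post-den-emergence litter size.
Each rate carries a standard error used by the stochastic engine's
uncertainty model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Rate",
    "VitalRates",
    "AGE_CLASSES",
    "SEXES",
    "age_class",
]

SEXES = ("f", "m")
AGE_CLASSES = ("coy", "yearling", "subadult", "adult")

#: Oldest dependent-young age; cubs disperse from their mother after the
#: season in which they are two years old (the three-year cycle).
DISPERSAL_AGE = 2


def age_class(age: int) -> str:
    """Map a whole-year age to its survival age class.

    Cub-of-year (0), yearling (1), subadult (2-4), adult (5+).
    """
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    if age == 0:
        return "coy"
    if age == 1:
        return "yearling"
    if age <= 4:
        return "subadult"
    return "adult"


@dataclass(frozen=True)
class Rate:
    """A rate estimate: mean with standard error."""

    mean: float
    se: float = 0.0

    def __post_init__(self):
        if self.se < 0:
            raise ValueError(f"SE must be nonnegative, got {self.se}")


@dataclass(frozen=True)
class VitalRates:
    """Sex/age-class survival and recruitment parameters for one subpopulation.

    Parameters
    ----------
    subpop_id : str
        Subpopulation label (e.g. "GB").
    survival : dict[(sex, age_class), Rate]
        Annual survival probability per (sex, age class).  Sexes are
        ``"f"``/``"m"``; classes are ``"coy"``, ``"yearling"``,
        ``"subadult"``, ``"adult"``.  Every (sex, class) pair must be
        present.
    rate_variant : {"natural", "total"}
        Whether survival excludes ("natural") or includes ("total")
        human-caused mortality.
    litter_production : dict[int, Rate]
        Annual probability that an available female of the given age
        produces a litter.  Ages not present have probability zero.
    litter_size : Rate
        Mean cubs per litter at den emergence, in [1, 3].
    cub_sex_ratio : float
        Probability a cub is female at birth.
    max_age : int
        Terminal age class; bears of this age or older share the adult
        rates (the class is absorbing, so survival 1 implies growth 1).
    """

    subpop_id: str
    survival: dict
    rate_variant: str = "natural"
    litter_production: dict = field(default_factory=dict)
    litter_size: Rate = Rate(2.0, 0.0)
    cub_sex_ratio: float = 0.5
    max_age: int = 30

    def __post_init__(self):
        if self.rate_variant not in ("natural", "total"):
            raise ValueError(f"unknown rate_variant {self.rate_variant!r}")
        if self.max_age < 5:
            raise ValueError("max_age must be at least 5")
        for sex in SEXES:
            for cls in AGE_CLASSES:
                if (sex, cls) not in self.survival:
                    raise ValueError(f"missing survival rate for {(sex, cls)}")
        for key, rate in self.survival.items():
            if not (0.0 <= rate.mean <= 1.0):
                raise ValueError(f"survival mean for {key} outside [0,1]: {rate.mean}")
        for age, rate in self.litter_production.items():
            if not (0.0 <= rate.mean <= 1.0):
                raise ValueError(
                    f"litter production mean at age {age} outside [0,1]: {rate.mean}"
                )
        if not (1.0 <= self.litter_size.mean <= 3.0):
            raise ValueError(f"litter size mean outside [1,3]: {self.litter_size.mean}")
        if not (0.0 <= self.cub_sex_ratio <= 1.0):
            raise ValueError("cub_sex_ratio outside [0,1]")

    # -- convenience views ------------------------------------------------

    @property
    def n_ages(self) -> int:
        return self.max_age + 1

    def survival_means(self, sex: str) -> np.ndarray:
        """Mean annual survival by whole-year age, shape (max_age+1,)."""
        return np.array(
            [self.survival[(sex, age_class(a))].mean for a in range(self.n_ages)]
        )

    def lpr_means(self) -> np.ndarray:
        """Mean litter-production probability by female age, shape (max_age+1,)."""
        out = np.zeros(self.n_ages)
        for age, rate in self.litter_production.items():
            if 0 <= age <= self.max_age:
                out[age] = rate.mean
        return out

    def with_variant(self, variant: str) -> "VitalRates":
        return replace(self, rate_variant=variant)

    def parameters(self):
        """Enumerate uncertain parameters as (name, mean, se, low, high).

        The order is fixed (survival by sex/class, litter production by
        age, then litter size) so that correlated draws are reproducible.
        """
        params = []
        for sex in SEXES:
            for cls in AGE_CLASSES:
                r = self.survival[(sex, cls)]
                params.append((f"survival:{sex}:{cls}", r.mean, r.se, 0.0, 1.0))
        for age in sorted(self.litter_production):
            r = self.litter_production[age]
            params.append((f"lpr:{age}", r.mean, r.se, 0.0, 1.0))
        params.append(
            ("litter_size", self.litter_size.mean, self.litter_size.se, 1.0, 3.0)
        )
        return params


def uniform_survival(
    value: float, se: float = 0.0, *, by_class: dict | None = None
) -> dict:
    """Build a survival table with one value everywhere, with optional
    per-class overrides like ``{"coy": 0.6}`` (applied to both sexes)."""
    table = {}
    for sex in SEXES:
        for cls in AGE_CLASSES:
            v = (by_class or {}).get(cls, value)
            table[(sex, cls)] = v if isinstance(v, Rate) else Rate(v, se)
    return table
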