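"""Closed-form outgrowth probabilities for the linear birth-death model of
disseminated tumour cells (DTCs) in bone.

A DTC lineage is a continuous-time Markov branching process in which every
cell independently divides at per-capita rate ``birth_rate`` (lambda) and
dies at per-capita rate ``death_rate`` (mu).  The quantity that governs
lineage fate is the ratio of death to proliferation rate,

    ratio = death_rate / birth_rate,

here exposed as :attr:`BranchingParams.ratio`.  A single founder's lineage
goes extinct with probability ``min(ratio, 1)``: extinction is certain at or
above criticality (ratio >= 1) and a supercritical lineage (ratio < 1)
escapes to indefinite growth with probability ``1 - ratio``.

For an animal seeded with ``n`` founders, of which only a fraction ``f``
(the proliferative fraction) are intrinsically capable of proliferating, the
probability that at least one lineage escapes - i.e. that an overt
metastatic lesion ("tumor") eventually forms - is

    P(tumor) = 1 - ((1 - f) + f * min(ratio, 1)) ** n        (mixture form)

which reduces to the classic ``1 - ratio**n`` when f = 1.  An alternative
formulation that scales the exponent by the expected number of proliferative
founders,

    P(tumor) = 1 - min(ratio, 1) ** (f * n)                  (exponent form)

is provided for comparison; the mixture form is exact under per-founder
independence and is the default everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "BranchingParams",
    "lineage_extinction_prob",
    "extinction_prob_at_time",
    "p_tumor",
    "p_tumor_curve",
    "MODEL_VARIANTS",
]

MODEL_VARIANTS = ("mixture", "exponent")


@dataclass(frozen=True)
class BranchingParams:
    """Per-capita rates of the linear birth-death process.

    Parameters
    ----------
    birth_rate
        Per-capita proliferation rate (events per cell per unit time;
        time units are arbitrary and never mapped to calendar time).
    death_rate
        Per-capita death rate, same units.
    proliferative_fraction
        Fraction ``f`` in [0, 1] of founder cells intrinsically capable of
        proliferating.  Non-proliferative founders never divide and cannot
        seed outgrowth.
    """

    birth_rate: float
    death_rate: float
    proliferative_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("birth_rate and death_rate must be non-negative")
        if self.birth_rate == 0 and self.death_rate == 0:
            raise ValueError("birth_rate and death_rate cannot both be zero")
        if not 0.0 <= self.proliferative_fraction <= 1.0:
            raise ValueError("proliferative_fraction must lie in [0, 1]")

    @property
    def ratio(self) -> float:
        """Death-to-birth rate ratio; +inf when birth_rate == 0."""
        if self.birth_rate == 0:
            return math.inf
        return self.death_rate / self.birth_rate

    @classmethod
    def from_ratio(
        cls,
        ratio: float,
        proliferative_fraction: float = 1.0,
        birth_rate: float = 1.0,
    ) -> "BranchingParams":
        """Build params from the dimensionless ratio alone.

        Outgrowth probabilities depend on (birth_rate, death_rate) only
        through their ratio, so birth_rate = 1 fixes the (arbitrary)
        time unit without loss of generality.
        """
        if ratio < 0:
            raise ValueError("ratio must be non-negative")
        return cls(
            birth_rate=birth_rate,
            death_rate=ratio * birth_rate,
            proliferative_fraction=proliferative_fraction,
        )


def lineage_extinction_prob(params: BranchingParams) -> float:
    """Probability that a single proliferative founder's lineage dies out.

    Equals ``min(ratio, 1)``: the smallest fixed point of the offspring
    probability generating function of the embedded branching process.
    """
    return min(params.ratio, 1.0)


def extinction_prob_at_time(t: float, params: BranchingParams) -> float:
    """Probability that a single founder's lineage is extinct by time ``t``.

    Standard linear birth-death result (solution of the PGF equation):

        q(t) = mu (e^{(lam-mu) t} - 1) / (lam e^{(lam-mu) t} - mu),  lam != mu
        q(t) = lam t / (1 + lam t),                                  lam == mu

    q is 0 at t = 0, non-decreasing, and converges to ``min(ratio, 1)``.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    lam, mu = params.birth_rate, params.death_rate
    if t == 0:
        return 0.0
    if lam == mu:
        return lam * t / (1.0 + lam * t)
    d = lam - mu
    # guard exp overflow: for large (lam-mu) t the limit min(ratio, 1) is
    # reached to double precision long before exp overflows
    if d * t > 700.0:
        return lineage_extinction_prob(params)
    e = math.exp(d * t)
    q = mu * (e - 1.0) / (lam * e - mu)
    return min(max(q, 0.0), 1.0)


def _check_count(n) -> int:
    if isinstance(n, bool):
        raise TypeError("n must be an integer count")
    if isinstance(n, float):
        if not n.is_integer():
            raise ValueError(f"n must be an integer count, got {n}")
        n = int(n)
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    return n


def p_tumor(n, params: BranchingParams, variant: str = "mixture") -> float:
    """Probability that ``n`` founder DTCs produce an overt lesion.

    Under the mixture form (default) each founder is independently
    proliferative with probability f, and a proliferative lineage escapes
    extinction with probability ``1 - min(ratio, 1)``, so

        P(tumor) = 1 - ((1 - f) + f * min(ratio, 1)) ** n.

    The exponent form instead uses ``1 - min(ratio, 1) ** (f n)``.
    Both return 0 whenever ratio >= 1, f = 0 or n = 0, and the mixture
    form reduces exactly to ``1 - ratio**n`` when f = 1.
    """
    n = _check_count(n)
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"variant must be one of {MODEL_VARIANTS}, got {variant!r}")
    q = lineage_extinction_prob(params)
    f = params.proliferative_fraction
    if n == 0:
        return 0.0
    if variant == "mixture":
        return 1.0 - ((1.0 - f) + f * q) ** n
    # exponent form; 0**0 == 1 handles q = 0 with f*n = 0
    return 1.0 - q ** (f * n)


def p_tumor_curve(
    n_values: Iterable[int],
    params: BranchingParams,
    variant: str = "mixture",
) -> list[tuple[int, float]]:
    """Element-wise :func:`p_tumor` over founder counts, order preserved."""
    return [(int(n), p_tumor(n, params, variant=variant)) for n in n_values]
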