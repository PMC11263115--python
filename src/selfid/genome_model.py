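"""Genotype → phenotype → fitness model for a selfing-rate quantitative trait.

The model organism is a hermaphroditic diploid with a single chromosome pair
of map length scaled to 1. Two classes of variation live on the chromosome:

* ``n_z`` additive trait loci at fixed positions ``0, 1/n_z, ..., (n_z-1)/n_z``
  with two alleles each. Allele ``A`` contributes ``-1/n_z`` and allele ``a``
  contributes ``+1/n_z`` to the phenotype ``z``, so ``z`` is confined to
  ``[-2, 2]`` regardless of ``n_z``. The individual selfing rate is a logistic
  function of ``z``: ``alpha = 1 / (1 + exp(-k (z - z_c)))``.
* Deleterious mutations under the infinite-sites model: every mutation occurs
  at a unique real-valued position in ``(0, 1)`` (trait-locus positions are
  excluded), with identical selection coefficient ``s`` and dominance ``h``.

Fitness is multiplicative across the two classes: stabilizing viability
selection on the trait, ``w1(z) = exp(-lambda z^2)``, times the deleterious
component ``w2 = (1-hs)^n_het (1-s)^n_hom``, so ``w = w1 * w2``.

Everything in this module is a pure function of genotypes and parameters;
random processes (mutation, meiosis, mate choice) live in
:mod:`selfid.sim_engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy.special import expit

__all__ = [
    "SimParams",
    "Haplotype",
    "Individual",
    "trait_phenotype",
    "selfing_rate",
    "viability_fitness",
    "deleterious_fitness",
    "zygosity_counts",
    "trait_locus_positions",
]


@dataclass(frozen=True)
class SimParams:
    """All model constants for one simulation run.

    Parameters
    ----------
    N : int
        Adult population size (constant, non-overlapping generations).
    U : float
        Diploid genomic deleterious mutation rate per generation. Each gamete
        receives ``Poisson(U/2)`` new mutations.
    s : float
        Selection coefficient of deleterious mutations, in ``[0, 1]``.
    h : float
        Dominance coefficient, in ``[0, 1]`` (``h < 0.5`` = partially
        recessive).
    L : float
        Expected number of crossovers per meiosis (map length in Morgans).
    n_z : int
        Number of additive loci controlling the selfing-related trait.
    U_z : float
        Diploid mutation rate of the trait; each gamete receives
        ``Poisson(U_z/2)`` allele-flip events.
    k : float
        Steepness of the logistic phenotype-to-selfing-rate map.
    z_c : float
        Phenotype at which the selfing rate equals 0.5; shifting ``z_c``
        shifts the mean selfing rate of the population.
    lam : float
        Strength of stabilizing viability selection on the trait
        (``lambda`` in ``w1 = exp(-lambda z^2)``).
    generations : int
        Number of generations to iterate.
    window : int
        Trailing window (in generations) over which equilibrium metrics are
        averaged.
    seed : int
        Seed of the run's random stream; identical seed and parameters
        reproduce the trajectory exactly.
    """

    N: int = 1000
    U: float = 0.5
    s: float = 0.2
    h: float = 0.1
    L: float = 10.0
    n_z: int = 10
    U_z: float = 0.2
    k: float = 3.0
    z_c: float = 0.0
    lam: float = 0.5
    generations: int = 1500
    window: int = 500
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.N >= 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        for name in ("U", "U_z", "L", "lam", "k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("s", "h"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {getattr(self, name)}")
        if not self.n_z >= 1:
            raise ValueError(f"n_z must be >= 1, got {self.n_z}")
        if not self.generations >= 1:
            raise ValueError(f"generations must be >= 1, got {self.generations}")
        if not 0 < self.window <= self.generations:
            raise ValueError(
                f"window must satisfy 0 < window <= generations, got {self.window}"
            )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


def trait_locus_positions(n_z: int) -> np.ndarray:
    """Chromosomal positions of the ``n_z`` trait loci: ``l / n_z``."""
    return np.arange(n_z, dtype=np.float64) / n_z


@dataclass
class Haplotype:
    """One chromosome: trait alleles plus deleterious-mutation positions.

    ``trait_alleles`` stores ``+1`` for allele ``a`` (effect ``+1/n_z``) and
    ``-1`` for allele ``A`` (effect ``-1/n_z``); the ``1/n_z`` scaling is
    applied at phenotype evaluation. ``del_positions`` is a strictly
    increasing float array of infinite-sites mutation positions in ``(0, 1)``
    that never coincide with a trait-locus position.
    """

    trait_alleles: np.ndarray
    del_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.float64)
    )

    def __post_init__(self) -> None:
        self.trait_alleles = np.ascontiguousarray(self.trait_alleles, dtype=np.int8)
        self.del_positions = np.ascontiguousarray(self.del_positions, dtype=np.float64)

    def validate(self, n_z: int | None = None) -> None:
        if n_z is not None and self.trait_alleles.size != n_z:
            raise ValueError(
                f"expected {n_z} trait alleles, got {self.trait_alleles.size}"
            )
        if not np.all(np.isin(self.trait_alleles, (-1, 1))):
            raise ValueError("trait alleles must be +/-1")
        p = self.del_positions
        if p.size:
            if not (np.all(p > 0.0) and np.all(p < 1.0)):
                raise ValueError("deleterious positions must lie in (0, 1)")
            if not np.all(np.diff(p) > 0):
                raise ValueError("deleterious positions must be strictly increasing")
            nz = self.trait_alleles.size
            if np.any(np.isin(p, trait_locus_positions(nz))):
                raise ValueError("deleterious position collides with a trait locus")

    def copy(self) -> "Haplotype":
        return Haplotype(self.trait_alleles.copy(), self.del_positions.copy())


def trait_phenotype(hap1: Haplotype, hap2: Haplotype, n_z: int) -> float:
    """Additive trait phenotype ``z`` of a diploid genotype.

    Each of the ``2 n_z`` allele copies contributes ``+/- 1/n_z``, so
    ``z`` lies in ``[-2, 2]``.
    """
    if hap1.trait_alleles.size != n_z or hap2.trait_alleles.size != n_z:
        raise ValueError(
            f"haplotypes must carry exactly n_z={n_z} trait alleles "
            f"(got {hap1.trait_alleles.size} and {hap2.trait_alleles.size})"
        )
    total = int(hap1.trait_alleles.sum()) + int(hap2.trait_alleles.sum())
    return total / n_z


def selfing_rate(z, k: float, z_c: float):
    """Logistic map from trait phenotype to individual selfing rate.

    ``alpha = 1 / (1 + exp(-k (z - z_c)))``; at ``z = z_c`` the selfing rate
    is exactly 0.5, and for ``k > 0`` the map is strictly increasing in ``z``.
    Accepts scalars or arrays.
    """
    return expit(k * (np.asarray(z, dtype=np.float64) - z_c))[()]


def viability_fitness(z, lam: float):
    """Stabilizing-selection viability ``w1(z) = exp(-lam * z**2)``."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    z = np.asarray(z, dtype=np.float64)
    return np.exp(-lam * z * z)[()]


def deleterious_fitness(n_het, n_hom, s: float, h: float):
    """Multiplicative fitness of deleterious mutations.

    ``w2 = (1 - h s)^n_het * (1 - s)^n_hom`` for ``n_het`` heterozygous and
    ``n_hom`` homozygous mutations. Accepts scalar or array counts.
    """
    n_het = np.asarray(n_het)
    n_hom = np.asarray(n_hom)
    return ((1.0 - h * s) ** n_het * (1.0 - s) ** n_hom)[()]


def zygosity_counts(hap1: Haplotype, hap2: Haplotype) -> tuple[int, int, float]:
    """Heterozygous/homozygous deleterious-mutation counts of a genotype.

    Returns ``(n_het, n_hom, fraction)`` where ``n_hom`` is the number of
    positions carried by both haplotypes, ``n_het`` the number carried by
    exactly one, and ``fraction = n_hom / (n_hom + n_het)`` (0 for a
    mutation-free genotype) is the individual homozygosity.
    """
    p1, p2 = hap1.del_positions, hap2.del_positions
    n_hom = int(np.intersect1d(p1, p2, assume_unique=True).size)
    n_het = int(p1.size + p2.size - 2 * n_hom)
    tot = n_het + n_hom
    frac = n_hom / tot if tot else 0.0
    return n_het, n_hom, frac


@dataclass
class Individual:
    """A diploid individual with its derived phenotype and fitness fields."""

    hap1: Haplotype
    hap2: Haplotype
    z: float
    alpha: float
    n_het: int
    n_hom: int
    w1: float
    w2: float
    w: float

    @classmethod
    def from_haplotypes(
        cls, hap1: Haplotype, hap2: Haplotype, params: SimParams
    ) -> "Individual":
        z = trait_phenotype(hap1, hap2, params.n_z)
        alpha = float(selfing_rate(z, params.k, params.z_c))
        n_het, n_hom, _ = zygosity_counts(hap1, hap2)
        w1 = float(viability_fitness(z, params.lam))
        w2 = float(deleterious_fitness(n_het, n_hom, params.s, params.h))
        return cls(hap1, hap2, z, alpha, n_het, n_hom, w1, w2, w1 * w2)

    @property
    def homozygosity(self) -> float:
        tot = self.n_het + self.n_hom
        return self.n_hom / tot if tot else 0.0
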