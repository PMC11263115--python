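"""Life cycle and run protocol of the forward-time simulator.

One generation is: reproduction (each offspring picks a uniform mother, who
selfs with probability equal to her selfing rate ``alpha`` or outcrosses
with a uniform second parent), meiosis (Poisson(L) crossovers at uniform
positions, Poisson(U/2) new deleterious mutations and Poisson(U_z/2) trait
allele flips per gamete), and viability selection (N juveniles resampled to
N adults with replacement, probability proportional to fitness).

The population lives in flat numpy arrays (see :mod:`selfid._kernels`); the
:class:`Population` wrapper exposes derived per-individual arrays and can
materialize :class:`~selfid.genome_model.Individual` objects for inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, id_metrics
from .genome_model import (
    Haplotype,
    Individual,
    SimParams,
    deleterious_fitness,
    selfing_rate,
    viability_fitness,
)

__all__ = [
    "RNGStream",
    "Population",
    "ExtinctionError",
    "SimResult",
    "initialize_population",
    "make_gamete",
    "recombine_haplotypes",
    "sample_breakpoints",
    "sample_new_mutation_counts",
    "choose_mode_and_parents",
    "make_offspring",
    "viability_selection",
    "step_generation",
    "run_simulation",
]

logger = logging.getLogger(__name__)

_SEED_MAX = 2**31 - 1


class ExtinctionError(RuntimeError):
    """All juveniles had zero fitness; the population went extinct."""

    def __init__(self, generation: int):
        super().__init__(f"population extinct at generation {generation}")
        self.generation = generation


class RNGStream:
    """A seeded stream of randomness for one simulation run.

    Python-level draws use a PCG64 generator; compiled kernels are seeded
    with child seeds drawn from the same generator, so an identical seed and
    parameter set reproduces a trajectory exactly.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.generator = np.random.default_rng(self.seed)

    def child_seed(self) -> int:
        return int(self.generator.integers(0, _SEED_MAX))


class Population:
    """N adults as flat arrays, with derived per-individual quantities.

    Attributes
    ----------
    trait : int8[N, 2, n_z]
        Trait alleles per individual and haplotype.
    positions, offsets :
        Flat sorted deleterious-mutation positions and per-haplotype offsets.
    z, alpha, n_het, n_hom, w1, w2, w :
        Derived arrays of length N.
    """

    def __init__(
        self,
        trait: np.ndarray,
        positions: np.ndarray,
        offsets: np.ndarray,
        params: SimParams,
        generation: int = 0,
    ):
        self.trait = np.ascontiguousarray(trait, dtype=np.int8)
        self.positions = np.ascontiguousarray(positions, dtype=np.float64)
        self.offsets = np.ascontiguousarray(offsets, dtype=np.int64)
        self.params = params
        self.generation = generation
        self.z = self.trait.sum(axis=(1, 2)).astype(np.float64) / params.n_z
        self.alpha = np.asarray(selfing_rate(self.z, params.k, params.z_c))
        self.n_het, self.n_hom = _kernels.zygosity_batch(self.positions, self.offsets)
        self.w1 = np.asarray(viability_fitness(self.z, params.lam))
        self.w2 = np.asarray(
            deleterious_fitness(self.n_het, self.n_hom, params.s, params.h)
        )
        self.w = self.w1 * self.w2

    @property
    def N(self) -> int:
        return self.trait.shape[0]

    def __len__(self) -> int:
        return self.N

    @property
    def mutation_copies(self) -> np.ndarray:
        """Total deleterious mutation copies per individual (het + 2*hom)."""
        return self.n_het + 2 * self.n_hom

    @property
    def homozygosity(self) -> np.ndarray:
        """Per-individual n_hom / (n_hom + n_het), 0 for mutation-free."""
        tot = self.n_het + self.n_hom
        with np.errstate(invalid="ignore"):
            frac = np.where(tot > 0, self.n_hom / np.maximum(tot, 1), 0.0)
        return frac

    def haplotype(self, i: int, g: int) -> Haplotype:
        lo = self.offsets[2 * i + g]
        hi = self.offsets[2 * i + g + 1]
        return Haplotype(self.trait[i, g].copy(), self.positions[lo:hi].copy())

    def individual(self, i: int) -> Individual:
        return Individual.from_haplotypes(
            self.haplotype(i, 0), self.haplotype(i, 1), self.params
        )

    def subset(self, indices: np.ndarray, generation: int | None = None) -> "Population":
        indices = np.asarray(indices, dtype=np.int64)
        n = indices.size
        sizes = np.empty(2 * n, dtype=np.int64)
        for o, i in enumerate(indices):
            sizes[2 * o] = self.offsets[2 * i + 1] - self.offsets[2 * i]
            sizes[2 * o + 1] = self.offsets[2 * i + 2] - self.offsets[2 * i + 1]
        offsets = np.zeros(2 * n + 1, dtype=np.int64)
        np.cumsum(sizes, out=offsets[1:])
        positions = np.empty(offsets[-1], dtype=np.float64)
        for o, i in enumerate(indices):
            lo, hi = self.offsets[2 * i], self.offsets[2 * i + 2]
            positions[offsets[2 * o] : offsets[2 * o + 2]] = self.positions[lo:hi]
        gen = self.generation if generation is None else generation
        return Population(self.trait[indices], positions, offsets, self.params, gen)

    @classmethod
    def from_individuals(
        cls, individuals: list[Individual], params: SimParams, generation: int = 0
    ) -> "Population":
        n = len(individuals)
        trait = np.empty((n, 2, params.n_z), dtype=np.int8)
        chunks: list[np.ndarray] = []
        offsets = np.zeros(2 * n + 1, dtype=np.int64)
        for i, ind in enumerate(individuals):
            for g, hap in enumerate((ind.hap1, ind.hap2)):
                hap.validate(params.n_z)
                trait[i, g] = hap.trait_alleles
                chunks.append(hap.del_positions)
                offsets[2 * i + g + 1] = offsets[2 * i + g] + hap.del_positions.size
        positions = (
            np.concatenate(chunks) if chunks else np.empty(0, dtype=np.float64)
        )
        return cls(trait, positions, offsets, params, generation)


@dataclass
class SimResult:
    """Outcome of :func:`run_simulation`.

    ``records`` holds one row per generation (see
    :data:`selfid.id_metrics.RECORD_COLUMNS`); assay-based columns are NaN in
    generations where no family assay was scheduled. ``final`` is the adult
    population after the last generation.
    """

    records: pd.DataFrame
    final: Population
    params: SimParams


def initialize_population(params: SimParams, rng: RNGStream) -> Population:
    """Mutation-free founding population with random trait alleles.

    Every trait-allele copy is independently ``a`` (+1) or ``A`` (-1) with
    probability 1/2, so the initial mean phenotype is 0 in expectation.
    """
    trait = (
        rng.generator.integers(0, 2, size=(params.N, 2, params.n_z), dtype=np.int8)
        * 2
        - 1
    )
    positions = np.empty(0, dtype=np.float64)
    offsets = np.zeros(2 * params.N + 1, dtype=np.int64)
    return Population(trait, positions, offsets, params, generation=0)


def make_gamete(parent: Individual, params: SimParams, rng: RNGStream) -> Haplotype:
    """One meiotic product of ``parent``, including new mutations."""
    pos, tr = _kernels.gamete_seeded(
        parent.hap1.del_positions,
        parent.hap2.del_positions,
        parent.hap1.trait_alleles,
        parent.hap2.trait_alleles,
        params.L,
        params.U,
        params.U_z,
        params.n_z,
        rng.child_seed(),
    )
    return Haplotype(tr, pos)


def recombine_haplotypes(
    hap1: Haplotype,
    hap2: Haplotype,
    breakpoints: np.ndarray,
    start: int,
    n_z: int,
) -> Haplotype:
    """Deterministic recombinant for given breakpoints and starting haplotype.

    Exposed for inspection and testing of the segment-walk logic; the
    stochastic path draws ``breakpoints ~ sorted U(0,1)^Poisson(L)`` and
    ``start ~ Bernoulli(1/2)`` around this same primitive.
    """
    pos, tr = _kernels.recombine_given(
        hap1.del_positions,
        hap2.del_positions,
        hap1.trait_alleles,
        hap2.trait_alleles,
        np.ascontiguousarray(breakpoints, dtype=np.float64),
        int(start),
        n_z,
    )
    return Haplotype(tr, pos)


def sample_breakpoints(n: int, L: float, rng: RNGStream):
    """Crossover counts and pooled positions over ``n`` meioses."""
    return _kernels.breakpoints_seeded(n, L, rng.child_seed())


def sample_new_mutation_counts(n: int, params: SimParams, rng: RNGStream):
    """New-mutation counts per diploid offspring over ``n`` offspring.

    Offspring of mutation-free parents carry only new mutations, so the
    count is read off the assembled gametes of the production meiosis path.
    Returns ``(counts, positions)``.
    """
    return _kernels.offspring_new_mutation_counts(
        n, params.L, params.U, params.U_z, params.n_z, rng.child_seed()
    )


def choose_mode_and_parents(adults: Population, rng: RNGStream):
    """Sample a mother, the selfing/outcrossing decision, and a father.

    The mother is uniform over adults; with probability ``alpha_mother`` the
    offspring is selfed (no father), otherwise a uniform father distinct
    from the mother is drawn. Returns ``(i, mode, j_or_None)``.
    """
    if adults.N < 2:
        raise ValueError("need at least 2 adults to choose parents")
    i = int(rng.generator.integers(adults.N))
    eps = rng.generator.random()
    if eps < adults.alpha[i]:
        return i, "self", None
    j = int(rng.generator.integers(adults.N - 1))
    if j >= i:
        j += 1
    return i, "outcross", j


def make_offspring(
    adults: Population, params: SimParams, rng: RNGStream
) -> Individual:
    """One juvenile: two gametes, from one parent (selfing) or two."""
    i, mode, j = choose_mode_and_parents(adults, rng)
    mother = adults.individual(i)
    gam1 = make_gamete(mother, params, rng)
    other = mother if mode == "self" else adults.individual(j)
    gam2 = make_gamete(other, params, rng)
    return Individual.from_haplotypes(gam1, gam2, params)


def viability_selection(juveniles: Population, N: int, rng: RNGStream) -> Population:
    """Resample N adults with replacement, probability proportional to w."""
    total = juveniles.w.sum()
    if not total > 0:
        raise ExtinctionError(juveniles.generation)
    idx = rng.generator.choice(juveniles.N, size=N, p=juveniles.w / total)
    return juveniles.subset(idx)


def step_generation(
    state: Population, params: SimParams, rng: RNGStream
) -> Population:
    """Advance one generation (batched kernel path)."""
    ok, trait, pos, off = _kernels.advance_generation_seeded(
        state.trait,
        state.positions,
        state.offsets,
        state.alpha,
        params.s,
        params.h,
        params.L,
        params.U,
        params.U_z,
        params.n_z,
        params.lam,
        rng.child_seed(),
    )
    if not ok:
        raise ExtinctionError(state.generation + 1)
    return Population(trait, pos, off, params, generation=state.generation + 1)


def run_simulation(
    params: SimParams,
    *,
    assay_cadence: int = 1,
    assay_start: int = 0,
    rng: RNGStream | None = None,
) -> SimResult:
    """Run the full protocol and record per-generation metrics.

    A family assay (selfed + outcrossed offspring per adult; see
    :func:`selfid.id_metrics.family_assay`) is performed every
    ``assay_cadence``-th generation once ``generation > assay_start``;
    other generations carry NaN in the assay-based columns. Population
    composition metrics are recorded every generation.

    Raises :class:`ExtinctionError` (carrying the generation index) if all
    juveniles of some generation have zero fitness.
    """
    if assay_cadence < 1:
        raise ValueError(f"assay_cadence must be >= 1, got {assay_cadence}")
    if rng is None:
        rng = RNGStream(params.seed)
    pop = initialize_population(params, rng)
    rows = []
    debug = logger.isEnabledFor(logging.DEBUG)
    for gen in range(1, params.generations + 1):
        pop = step_generation(pop, params, rng)
        do_assay = gen > assay_start and gen % assay_cadence == 0
        if do_assay:
            w_self, w_out = _kernels.family_assay_kernel(
                pop.trait,
                pop.positions,
                pop.offsets,
                params.s,
                params.h,
                params.L,
                params.U,
                params.U_z,
                params.n_z,
                rng.child_seed(),
            )
        else:
            w_self = w_out = None
        rows.append(id_metrics.generation_metrics(pop, w_self, w_out))
        if gen % 1000 == 0:
            logger.info(
                "generation %d: alpha_bar=%.4f mean_copies=%.2f",
                gen,
                rows[-1]["alpha_bar"],
                rows[-1]["mean_mut_copies"],
            )
        if debug:
            logger.debug("generation %d: %s", gen, rows[-1])
    records = pd.DataFrame(rows, columns=id_metrics.RECORD_COLUMNS)
    return SimResult(records=records, final=pop, params=params)
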