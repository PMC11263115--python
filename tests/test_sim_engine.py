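"""Life-cycle operations: meiosis, mate choice, selection, run protocol."""

import numpy as np
import pytest
from scipy import stats

from selfid import (
    ExtinctionError,
    RNGStream,
    SimParams,
    initialize_population,
    make_gamete,
    make_offspring,
    run_simulation,
    step_generation,
    viability_selection,
)
from selfid.genome_model import Haplotype, Individual
from selfid.sim_engine import (
    Population,
    choose_mode_and_parents,
    recombine_haplotypes,
    sample_breakpoints,
    sample_new_mutation_counts,
)


def hap(alleles, positions=()):
    return Haplotype(np.asarray(alleles, np.int8), np.asarray(positions, float))


def clonal_population(params, hap1, hap2, n):
    ind = Individual.from_haplotypes(hap1, hap2, params)
    return Population.from_individuals(
        [Individual.from_haplotypes(hap1.copy(), hap2.copy(), params) for _ in range(n)],
        params,
    )


class TestInitializePopulation:
    def test_size_and_mutation_free(self, tiny_params, rng):
        pop = initialize_population(tiny_params, rng)
        assert pop.N == tiny_params.N
        assert pop.n_het.sum() == 0 and pop.n_hom.sum() == 0
        assert np.all(pop.w2 == 1.0)

    def test_mean_phenotype_near_zero(self):
        # symmetric Bernoulli draw of 2*n_z allele copies
        params = SimParams(N=2000, n_z=10, generations=10, window=5)
        zs = [
            initialize_population(params, RNGStream(seed)).z.mean()
            for seed in range(5)
        ]
        # SE of mean z is sqrt(2/n_z/N) ~ 0.01
        assert abs(np.mean(zs)) < 0.02


class TestMakeGamete:
    def test_no_crossover_no_mutation_copies_one_parent(self, rng):
        params = SimParams(N=10, L=0.0, U=0.0, U_z=0.0)
        h1 = hap(np.ones(10), [0.11, 0.31])
        h2 = hap(-np.ones(10), [0.51])
        parent = Individual.from_haplotypes(h1, h2, params)
        seen = set()
        for _ in range(200):
            g = make_gamete(parent, params, rng)
            key = tuple(g.del_positions)
            assert key in {(0.11, 0.31), (0.51,)}
            seen.add(key)
        assert len(seen) == 2  # both parental haplotypes occur

    def test_forced_crossover_at_half(self):
        h1 = hap(np.ones(10), [0.15, 0.35])
        h2 = hap(-np.ones(10), [0.55, 0.75])
        g = recombine_haplotypes(h1, h2, np.array([0.5]), start=0, n_z=10)
        assert np.allclose(g.del_positions, [0.15, 0.35, 0.55, 0.75])
        assert list(g.trait_alleles) == [1] * 5 + [-1] * 5
        g2 = recombine_haplotypes(h1, h2, np.array([0.5]), start=1, n_z=10)
        assert g2.del_positions.size == 0
        assert list(g2.trait_alleles) == [-1] * 5 + [1] * 5

    def test_new_mutation_rate(self, rng):
        params = SimParams(N=10, U=0.5)
        counts, _ = sample_new_mutation_counts(10**5, params, rng)
        mean = counts.mean()
        se = counts.std() / np.sqrt(counts.size)
        assert abs(mean - 0.5) < 3 * se

    def test_crossover_poisson_moments(self, rng):
        counts, _ = sample_breakpoints(2 * 10**4, 10.0, rng)
        se_mean = counts.std() / np.sqrt(counts.size)
        assert abs(counts.mean() - 10.0) < 3 * se_mean
        # Poisson variance ~ L; SE of the sample variance ~ sqrt(2/n)*var
        assert abs(counts.var() - 10.0) < 4 * np.sqrt(2.0 / counts.size) * 10.0

    def test_positions_uniform(self, rng):
        _, breaks = sample_breakpoints(2000, 5.0, rng)
        assert stats.kstest(breaks, "uniform").pvalue > 1e-3
        counts, muts = sample_new_mutation_counts(
            20000, SimParams(N=10, U=0.5), rng
        )
        assert stats.kstest(muts, "uniform").pvalue > 1e-3

    def test_gamete_respects_haplotype_invariants(self, rng):
        params = SimParams(N=10, U=3.0, U_z=1.0, L=2.0, n_z=10)
        h1 = hap(np.ones(10), [0.11, 0.31, 0.77])
        h2 = hap(-np.ones(10), [0.31, 0.51])
        parent = Individual.from_haplotypes(h1, h2, params)
        for _ in range(100):
            g = make_gamete(parent, params, rng)
            g.validate(params.n_z)


class TestChooseModeAndParents:
    def test_deterministic_extremes(self, rng):
        params = SimParams(N=20, k=1000.0, z_c=0.0, U=0.0)
        all_self = clonal_population(params, hap(np.ones(10)), hap(np.ones(10)), 20)
        assert np.all(all_self.alpha == 1.0)
        all_out = clonal_population(params, hap(-np.ones(10)), hap(-np.ones(10)), 20)
        assert np.all(all_out.alpha == 0.0)
        for _ in range(50):
            _, mode, j = choose_mode_and_parents(all_self, rng)
            assert mode == "self" and j is None
        for _ in range(50):
            i, mode, j = choose_mode_and_parents(all_out, rng)
            assert mode == "outcross" and j is not None and j != i

    def test_selfing_fraction_matches_alpha(self, rng):
        # z = 2, k and z_c tuned so alpha = logistic(k(2 - z_c)) = 0.7
        target = 0.7
        z_c = 2.0 - np.log(target / (1 - target)) / 3.0
        params = SimParams(N=20, k=3.0, z_c=z_c, U=0.0)
        pop = clonal_population(params, hap(np.ones(10)), hap(np.ones(10)), 20)
        assert pop.alpha[0] == pytest.approx(target)
        n = 10**5
        selfed = sum(
            choose_mode_and_parents(pop, rng)[1] == "self" for _ in range(n)
        )
        se = np.sqrt(target * (1 - target) / n)
        assert abs(selfed / n - target) < 3 * se

    def test_requires_two_adults(self, rng, tiny_params):
        solo = clonal_population(tiny_params, hap(np.ones(10)), hap(np.ones(10)), 1)
        with pytest.raises(ValueError):
            choose_mode_and_parents(solo, rng)


class TestMakeOffspring:
    def test_clone_under_no_mutation(self, rng):
        params = SimParams(N=5, U=0.0, U_z=0.0, k=1000.0)
        pop = clonal_population(params, hap(np.ones(10)), hap(np.ones(10)), 5)
        off = make_offspring(pop, params, rng)
        assert np.all(off.hap1.trait_alleles == 1)
        assert np.all(off.hap2.trait_alleles == 1)
        assert off.n_het == off.n_hom == 0

    def test_mendelian_segregation_when_selfing_het_parent(self, rng):
        params = SimParams(N=4, U=0.0, U_z=0.0, s=0.3, h=0.2, k=1000.0)
        h1 = hap(np.ones(10), [0.55])
        h2 = hap(np.ones(10))
        pop = clonal_population(params, h1, h2, 4)  # alpha = 1: always selfs
        counts = {"absent": 0, "het": 0, "hom": 0}
        n = 4000
        for _ in range(n):
            off = make_offspring(pop, params, rng)
            if off.n_hom:
                counts["hom"] += 1
            elif off.n_het:
                counts["het"] += 1
            else:
                counts["absent"] += 1
        for key, p in (("absent", 0.25), ("het", 0.5), ("hom", 0.25)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) < 4 * se


class TestViabilitySelection:
    def test_zero_fitness_never_sampled(self, rng):
        params = SimParams(N=10, s=1.0, h=0.0, U=0.0, lam=0.0)
        dead = Individual.from_haplotypes(
            hap(np.ones(10), [0.55]), hap(np.ones(10), [0.55]), params
        )
        alive = Individual.from_haplotypes(hap(np.ones(10)), hap(np.ones(10)), params)
        juveniles = Population.from_individuals([dead] + [alive] * 3, params)
        assert juveniles.w[0] == 0.0
        adults = viability_selection(juveniles, 50, rng)
        assert adults.n_hom.sum() == 0

    def test_sampling_proportional_to_fitness(self, rng):
        params = SimParams(N=10, s=0.8, h=0.125, U=0.0, lam=0.0)
        # one het mutation: w = 1 - h*s = 0.9 vs mutation-free w = 1.0
        weak = Individual.from_haplotypes(hap(np.ones(10), [0.55]), hap(np.ones(10)), params)
        strong = Individual.from_haplotypes(hap(np.ones(10)), hap(np.ones(10)), params)
        juveniles = Population.from_individuals([weak, strong], params)
        n = 10**5
        adults = viability_selection(juveniles, n, rng)
        p = 0.9 / 1.9
        frac_weak = adults.n_het.sum() / n
        assert abs(frac_weak - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_extinction_signalled(self, rng):
        params = SimParams(N=10, s=1.0, h=1.0, U=0.0, lam=0.0)
        dead = Individual.from_haplotypes(
            hap(np.ones(10), [0.55]), hap(np.ones(10), [0.55]), params
        )
        juveniles = Population.from_individuals([dead, dead], params)
        with pytest.raises(ExtinctionError):
            viability_selection(juveniles, 2, rng)


class TestStepGeneration:
    def test_population_size_conserved(self, tiny_params, rng):
        pop = initialize_population(tiny_params, rng)
        for _ in range(5):
            pop = step_generation(pop, tiny_params, rng)
            assert pop.N == tiny_params.N

    def test_no_mutation_input_never_increases_load(self, rng):
        params = SimParams(N=50, U=0.0, U_z=0.0, generations=10, window=5)
        h1 = hap(np.ones(10), [0.55])
        pop = clonal_population(params, h1, hap(np.ones(10)), 50)
        # without mutational input the set of segregating positions never grows
        n_seg = np.unique(pop.positions).size
        for _ in range(10):
            pop = step_generation(pop, params, rng)
            new_seg = np.unique(pop.positions).size
            assert new_seg <= n_seg
            n_seg = new_seg

    def test_neutral_accumulation_rate(self, rng):
        # s=0, lam=0: every juvenile survives equally; mean copies grow by U/gen
        params = SimParams(N=500, U=0.5, s=0.0, lam=0.0, U_z=0.0, generations=20, window=5)
        pop = initialize_population(params, rng)
        gens = 20
        for _ in range(gens):
            pop = step_generation(pop, params, rng)
        mean = pop.mutation_copies.mean()
        # E[mean] = U * gens; SE of the mean copy count across runs ~ sqrt(U*gens/N)
        assert abs(mean - params.U * gens) < 5 * np.sqrt(params.U * gens / params.N)

    def test_heterozygosity_halves_under_complete_selfing(self, rng):
        params = SimParams(N=300, U=0.0, U_z=0.0, s=0.0, lam=0.0, k=1000.0)
        h1 = hap(np.ones(10), np.linspace(0.051, 0.949, 40))
        pop = clonal_population(params, h1, hap(np.ones(10)), 300)
        assert np.all(pop.alpha == 1.0)
        means = [pop.n_het.mean()]
        for _ in range(3):
            pop = step_generation(pop, params, rng)
            means.append(pop.n_het.mean())
        for before, after in zip(means, means[1:]):
            assert after / before == pytest.approx(0.5, rel=0.15)

    def test_single_locus_selfing_selection_recursion(self, rng):
        # brute-force one-generation Mendelian + selection oracle for a
        # population of selfing single-locus heterozygotes
        s, h = 0.3, 0.2
        params = SimParams(N=5000, U=0.0, U_z=0.0, s=s, h=h, lam=0.0, k=1000.0)
        pop = clonal_population(params, hap(np.ones(10), [0.55]), hap(np.ones(10)), 5000)
        pop = step_generation(pop, params, rng)
        w_het, w_hom = 1 - h * s, 1 - s
        weights = np.array([0.25, 0.5 * w_het, 0.25 * w_hom])
        expected = weights / weights.sum()
        observed = np.array(
            [
                np.mean((pop.n_het == 0) & (pop.n_hom == 0)),
                np.mean(pop.n_het == 1),
                np.mean(pop.n_hom == 1),
            ]
        )
        se = np.sqrt(expected * (1 - expected) / pop.N)
        assert np.all(np.abs(observed - expected) < 4 * se)


class TestRunSimulation:
    def test_record_count_and_determinism(self):
        params = SimParams(N=80, generations=40, window=10, seed=99)
        a = run_simulation(params)
        b = run_simulation(params)
        assert len(a.records) == params.generations
        assert a.records.equals(b.records)
        assert np.array_equal(a.final.positions, b.final.positions)

    def test_different_seeds_differ(self):
        params = SimParams(N=80, generations=30, window=10, seed=1)
        a = run_simulation(params)
        b = run_simulation(SimParams(N=80, generations=30, window=10, seed=2))
        assert not a.records.equals(b.records)

    def test_neutral_mutations_give_zero_delta0(self):
        params = SimParams(N=100, s=0.0, generations=30, window=10, seed=5)
        res = run_simulation(params)
        assert np.all(res.records["delta0"] == 0.0)

    def test_assay_schedule(self):
        params = SimParams(N=60, generations=30, window=10, seed=5)
        res = run_simulation(params, assay_cadence=5, assay_start=10)
        d = res.records.set_index("generation")["delta0"]
        assert d.loc[[15, 20, 25, 30]].notna().all()
        assert d.loc[[5, 10, 12, 14]].isna().all()

    def test_outcrossing_limit_matches_mutation_selection_balance(self):
        # With alpha ~ 0 the equilibrium baseline ID approaches the classical
        # closed form delta0 = 1 - exp(-U (1 - 2h) / (4h)) under multiplicative
        # mutation-selection balance (independent of s).
        U, h, s = 0.2, 0.3, 0.2
        params = SimParams(
            N=1000, U=U, s=s, h=h, z_c=30.0, U_z=0.2, generations=600, window=200,
            seed=21,
        )
        res = run_simulation(params, assay_start=400)
        assert res.records["alpha_bar"].iloc[-1] < 1e-6
        predicted = 1.0 - np.exp(-U * (1 - 2 * h) / (4 * h))
        measured = res.records["delta0"].tail(200).mean()
        assert measured == pytest.approx(predicted, abs=0.02)
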