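"""The evolutionary loop: selection, variation, niching, front extraction."""

import numpy as np
import pytest
from scipy import stats

from paretomotif.core import Candidate, FitnessVector, ValidationError
from paretomotif.engine import (
    GAConfig,
    Population,
    evolve,
    initialize_population,
    local_refine,
    mutate,
    niche_count,
    one_point_crossover,
    pareto_front,
    pareto_tournament,
    shared_fitness,
)


def _pop_with_fitness(seqs, vectors):
    """Population of distinct members with a prescribed fitness cache."""
    members = [Candidate(8, (i,) + (0,) * (seqs.N - 1))
               for i in range(len(vectors))]
    return Population(seqs, members, np.asarray(vectors, dtype=float))


class TestInitialization:
    def test_count_and_candidate_validity(self, random_seqs):
        cfg = GAConfig(population_size=50, rng_seed=3)
        pop = initialize_population(random_seqs, cfg, np.random.default_rng(3))
        assert len(pop) == 50
        for cand in pop.members:
            cand.validate(random_seqs)

    def test_same_seed_gives_identical_population(self, random_seqs):
        cfg = GAConfig(population_size=30, rng_seed=9)
        a = initialize_population(random_seqs, cfg, np.random.default_rng(9))
        b = initialize_population(random_seqs, cfg, np.random.default_rng(9))
        assert a.members == b.members
        assert np.array_equal(a.fitness, b.fitness)

    def test_width_distribution_uniform(self, random_seqs):
        cfg = GAConfig(population_size=10000, rng_seed=1)
        pop = initialize_population(random_seqs, cfg, np.random.default_rng(1))
        widths = np.array([m.width for m in pop.members])
        observed = np.bincount(widths, minlength=21)[4:21]
        assert stats.chisquare(observed).pvalue > 1e-3

    def test_too_short_sequences_rejected(self, random_seqs):
        cfg = GAConfig(width_min=100, width_max=120)
        with pytest.raises(ValidationError):
            initialize_population(random_seqs, cfg, np.random.default_rng(0))


class TestNiching:
    def test_identical_vectors_all_share_one_niche(self, random_seqs):
        pop = _pop_with_fitness(random_seqs, [(0.5, 0.5)] * 5)
        assert all(niche_count(i, pop, 0.1) == 5 for i in range(5))

    def test_chebyshev_radius(self, random_seqs):
        pop = _pop_with_fitness(
            random_seqs, [(0.0, 0.0), (0.05, 0.0), (1.0, 1.0)])
        assert niche_count(0, pop, 0.1) == 2
        assert niche_count(2, pop, 0.1) == 1

    def test_self_count_at_least_one(self, random_seqs, rng):
        pop = _pop_with_fitness(random_seqs, rng.random((20, 2)))
        assert all(niche_count(i, pop, 1e-9) >= 1 for i in range(20))

    def test_shared_fitness_divides_components(self):
        f = FitnessVector(0.8, 0.4)
        assert shared_fitness(f, 1) == f
        s = shared_fitness(f, 4)
        assert (s.similarity, s.norm_length) == (0.2, 0.1)
        for q in (1, 2, 7):
            s = shared_fitness(f, q)
            assert s.similarity <= f.similarity and s.norm_length <= f.norm_length
        with pytest.raises(ValidationError):
            shared_fitness(f, 0)


class TestParetoTournament:
    def test_non_dominated_candidate_beats_dominated(self, random_seqs):
        # member 2 dominates member 0; member 1 trades off against everyone
        vectors = [(0.4, 0.4), (0.2, 0.9), (0.6, 0.5), (0.5, 0.1)]
        pop = _pop_with_fitness(random_seqs, vectors)
        cfg = GAConfig(population_size=4, t_dom=2, rng_seed=0)
        wins = 0
        for seed in range(20):
            winner = pareto_tournament(pop.members[0], pop.members[1], pop, cfg,
                                       np.random.default_rng(seed))
            wins += winner == pop.members[1]
        # whenever member 2 lands in the comparison set, candidate 0 is
        # dominated and candidate 1 must win; it can never lose to 0 on niching
        assert wins >= 10

    def test_tie_resolved_by_smaller_niche_count(self, random_seqs):
        # both candidates non-dominated; candidate 0 is in a crowd of 4
        vectors = [(0.2, 0.8), (0.21, 0.8), (0.19, 0.8), (0.2, 0.81),
                   (0.8, 0.2)]
        pop = _pop_with_fitness(random_seqs, vectors)
        cfg = GAConfig(population_size=5, t_dom=1, sigma_share=0.05, rng_seed=0)
        for seed in range(10):
            winner = pareto_tournament(pop.members[0], pop.members[4], pop, cfg,
                                       np.random.default_rng(seed))
            assert winner == pop.members[4]

    def test_seeded_tournament_reproducible(self, random_seqs):
        pop = _pop_with_fitness(random_seqs, [(0.5, 0.5)] * 6)
        cfg = GAConfig(population_size=6, t_dom=2, rng_seed=0)
        winners = {
            pareto_tournament(pop.members[0], pop.members[1], pop, cfg,
                              np.random.default_rng(4)).starts
            for _ in range(5)
        }
        assert len(winners) == 1


class TestCrossover:
    def test_tails_swapped_after_point(self, random_seqs):
        a = Candidate(8, (10, 20, 30, 40, 1, 2, 3, 4, 5, 6))
        b = Candidate(8, (50, 60, 70, 72, 7, 8, 9, 10, 11, 12))
        ca, cb = one_point_crossover(a, b, random_seqs,
                                     np.random.default_rng(0), k=2)
        assert ca.starts[:2] == (10, 20) and ca.starts[2:] == b.starts[2:]
        assert cb.starts[:2] == (50, 60) and cb.starts[2:] == a.starts[2:]

    def test_identical_parents_give_identical_offspring(self, random_seqs):
        p = Candidate(6, tuple([5] * 10))
        ca, cb = one_point_crossover(p, p, random_seqs, np.random.default_rng(1))
        assert ca == p and cb == p

    def test_inherited_start_clamped_to_sequence_end(self, random_seqs):
        # width-10 child inheriting start 74 on an 80-bp sequence -> 70
        a = Candidate(10, tuple([0] * 10))
        b = Candidate(4, tuple([74] * 10))
        ca, _ = one_point_crossover(a, b, random_seqs,
                                    np.random.default_rng(0), k=5)
        assert all(s == 70 for s in ca.starts[5:])
        ca.validate(random_seqs)

    def test_offspring_always_valid(self, random_seqs, rng):
        for _ in range(30):
            wa, wb = (int(x) for x in rng.integers(4, 21, size=2))
            a = Candidate(wa, tuple(int(x) for x in
                                    rng.integers(0, 81 - wa, size=10)))
            b = Candidate(wb, tuple(int(x) for x in
                                    rng.integers(0, 81 - wb, size=10)))
            for child in one_point_crossover(a, b, random_seqs, rng):
                child.validate(random_seqs)


class TestMutation:
    def test_zero_probabilities_leave_candidate_unchanged(self, random_seqs):
        cfg = GAConfig(mutation_prob=0.0, width_mutation_prob=0.0)
        cand = Candidate(8, tuple([3] * 10))
        assert mutate(cand, random_seqs, cfg, np.random.default_rng(0)) == cand

    def test_mutated_candidates_stay_valid(self, random_seqs, rng):
        cfg = GAConfig(mutation_prob=1.0, width_mutation_prob=0.5)
        cand = Candidate(20, tuple([60] * 10))
        for _ in range(50):
            cand = mutate(cand, random_seqs, cfg, rng)
            cand.validate(random_seqs)

    def test_seeded_mutation_reproducible(self, random_seqs):
        cfg = GAConfig(mutation_prob=1.0, width_mutation_prob=1.0)
        cand = Candidate(8, tuple([3] * 10))
        a = mutate(cand, random_seqs, cfg, np.random.default_rng(11))
        b = mutate(cand, random_seqs, cfg, np.random.default_rng(11))
        assert a == b


class TestLocalRefine:
    def test_similarity_never_decreases(self, random_seqs, rng):
        from paretomotif.core import fitness
        for _ in range(10):
            w = int(rng.integers(4, 15))
            cand = Candidate(w, tuple(int(x) for x in
                                      rng.integers(0, 81 - w, size=10)))
            before = fitness(cand, random_seqs).similarity
            after = fitness(local_refine(cand, random_seqs, rng),
                            random_seqs).similarity
            assert after >= before

    def test_locks_onto_planted_motif_from_partial_alignment(self, small_seqs):
        seqs, starts, _ = small_seqs
        # half the starts correct, half random: one sweep recovers the rest
        mixed = tuple(starts[i] if i < 3 else 0 for i in range(6))
        refined = local_refine(Candidate(8, mixed), seqs,
                               np.random.default_rng(5))
        assert refined.starts == tuple(starts)


class TestParetoFront:
    def test_matches_brute_force_dominance_oracle(self, random_seqs):
        for seed in range(3):
            cfg = GAConfig(population_size=150, rng_seed=seed)
            pop = initialize_population(random_seqs, cfg,
                                        np.random.default_rng(seed))
            front = pareto_front(pop)
            fits = pop.fitness
            oracle = set()
            for i in range(len(fits)):
                dominated = any(
                    (fits[j] >= fits[i]).all() and (fits[j] > fits[i]).any()
                    for j in range(len(fits)) if j != i)
                if not dominated:
                    oracle.add(i)
            oracle_widths = {pop.members[i].width for i in oracle}
            front_widths = {c.width for c in front}
            assert front_widths == oracle_widths
            member_index = {m: i for i, m in enumerate(pop.members)}
            for cand in front:
                assert any(pop.members[i] == cand for i in oracle)
            # every returned pair mutually non-inferior
            ff = np.array([fits[member_index[c]] for c in front])
            for i in range(len(ff)):
                for j in range(len(ff)):
                    if i != j:
                        assert not ((ff[i] >= ff[j]).all()
                                    and (ff[i] > ff[j]).any())

    def test_constructed_front(self, random_seqs):
        vectors = [(0.9, 0.2), (0.8, 0.5), (0.7, 0.4), (0.9, 0.5)]
        pop = _pop_with_fitness(random_seqs, vectors)
        front = pareto_front(pop)
        idx = [pop.members.index(c) for c in front]
        assert idx == [3] or [tuple(pop.fitness[i]) for i in idx] == [(0.9, 0.5)]

    def test_identical_population_collapses_to_one(self, random_seqs):
        cand = Candidate(8, tuple([3] * 10))
        pop = Population(random_seqs, [cand] * 6,
                         np.tile([0.5, 0.4], (6, 1)))
        assert pareto_front(pop) == [cand]


class TestEvolve:
    def test_huge_stagnation_eps_forces_early_stop(self, random_seqs):
        gens = []
        cfg = GAConfig(population_size=12, t_dom=3, stagnation_eps=1e9,
                       max_generations=100, rng_seed=0)
        evolve(random_seqs, cfg, on_generation=lambda g, m, f: gens.append(g))
        assert gens[-1] <= cfg.stagnation_generations + 1

    def test_fixed_seed_fixes_entire_run(self, small_seqs):
        seqs, _, _ = small_seqs
        cfg = GAConfig(population_size=20, t_dom=3, max_generations=15,
                       rng_seed=42)
        a = evolve(seqs, cfg)
        b = evolve(seqs, cfg)
        assert [(c, fv, s) for c, fv, s in a] == [(c, fv, s) for c, fv, s in b]

    def test_front_never_dominated_by_previous_front(self, small_seqs):
        seqs, _, _ = small_seqs
        fronts = []
        cfg = GAConfig(population_size=20, t_dom=3, max_generations=25,
                       rng_seed=1)
        evolve(seqs, cfg, on_generation=lambda g, m, f: fronts.append(f.copy()))
        for prev, cur in zip(fronts, fronts[1:]):
            for new_vec in cur:
                assert not any((old >= new_vec).all() and (old > new_vec).any()
                               for old in prev)

    def test_recovers_identical_planted_motif(self, small_seqs):
        seqs, starts, motif = small_seqs
        hits = 0
        for seed in range(10):
            cfg = GAConfig(population_size=60, t_dom=6, max_generations=100,
                           rng_seed=seed)
            front = evolve(seqs, cfg)
            for cand, fv, consensus in front:
                if cand.width == 8 and cand.starts == tuple(starts):
                    assert fv.similarity == 1.0
                    assert consensus == motif
                    hits += 1
                    break
        assert hits >= 9

    def test_all_generations_produce_valid_candidates(self, random_seqs):
        cfg = GAConfig(population_size=16, t_dom=3, max_generations=10,
                       rng_seed=2)
        front = evolve(random_seqs, cfg)
        for cand, fv, consensus in front:
            cand.validate(random_seqs)
            assert len(consensus) == cand.width
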