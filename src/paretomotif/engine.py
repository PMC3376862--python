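"""Niched Pareto genetic algorithm over candidate motifs.

Selection uses Pareto domination tournaments: each of two randomly drawn
candidates is compared against a random comparison set of ``t_dom``
population members; a candidate dominated by no set member wins outright.
When neither or both are non-dominated, fitness sharing breaks the tie —
the candidate with the smaller niche count (number of population members
within ``sigma_share`` of its fitness vector, Chebyshev distance in the
2-D objective space) is preferred, which pushes the population to spread
across the Pareto front instead of collapsing onto one optimum.

Replacement is generational with elitist carry-over of the current
non-dominated set, so the front can only improve from one generation to
the next.  The run stops on stagnation of the population-average fitness
or at the generation cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import (
    WIDTH_MAX,
    WIDTH_MIN,
    Candidate,
    FitnessVector,
    ProfileMatrix,
    SequenceSet,
    ValidationError,
    consensus_string,
    profile_counts,
    site_matrix,
)


@dataclass(frozen=True)
class GAConfig:
    """Tunable parameters of the evolutionary loop.

    ``t_dom`` is the Pareto-tournament comparison-set size (about 10% of
    the population); ``sigma_share`` the niche radius in objective space.
    Width bounds default to the 4–20 bp motif range.  ``width_mutation_prob``
    adds a +/-1 width drift so motif length can adapt after initialization;
    ``refine_prob`` is the chance an offspring receives one local-refinement
    pass (coordinate ascent over its start positions, see
    :func:`local_refine`); ``shift_prob`` the chance all of an offspring's
    starts slide together by a small offset, which escapes the phase-shift
    local optima coordinate ascent cannot leave.  Set the last three to 0
    for a pure random-variation search.
    """

    population_size: int = 100
    max_generations: int = 200
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    width_mutation_prob: float = 0.1
    refine_prob: float = 0.2
    shift_prob: float = 0.1
    t_dom: int = 10
    sigma_share: float = 0.1
    stagnation_eps: float = 1e-4
    stagnation_generations: int = 10
    width_min: int = WIDTH_MIN
    width_max: int = WIDTH_MAX
    rng_seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValidationError("population_size must be >= 4")
        for name in ("crossover_prob", "mutation_prob", "width_mutation_prob",
                     "refine_prob", "shift_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if not 1 <= self.t_dom < self.population_size:
            raise ValidationError("t_dom must satisfy 1 <= t_dom < population_size")
        if self.sigma_share <= 0:
            raise ValidationError("sigma_share must be positive")
        if not WIDTH_MIN <= self.width_min <= self.width_max:
            raise ValidationError("width bounds must satisfy 4 <= width_min <= width_max")


@dataclass
class Population:
    """Members with their cached fitness vectors, tied to a sequence set."""

    seqs: SequenceSet
    members: list[Candidate]
    fitness: np.ndarray  # shape (P, 2): columns similarity, norm_length
    generation: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def fitness_of(self, candidate: Candidate) -> np.ndarray:
        try:
            return self.fitness[self.members.index(candidate)]
        except ValueError:
            return _evaluate(candidate.width, np.asarray(candidate.starts), self.seqs)


@dataclass(frozen=True)
class SharingState:
    """Raw fitness, niche count and the derated (shared) fitness f_s = f / q."""

    raw: FitnessVector
    niche: int
    shared: FitnessVector = field(init=False)

    def __post_init__(self):
        if self.niche < 1:
            raise ValidationError("niche count must be >= 1 (self-inclusive)")
        object.__setattr__(
            self, "shared",
            FitnessVector(self.raw.similarity / self.niche,
                          self.raw.norm_length / self.niche),
        )


def _evaluate(width: int, starts: np.ndarray, seqs: SequenceSet,
              width_max: int = WIDTH_MAX) -> np.ndarray:
    mat = site_matrix(width, starts, seqs)
    counts = profile_counts(mat)
    sim = counts.max(axis=0).sum() / (seqs.N * width)
    return np.array([sim, width / width_max])


def _evaluate_all(widths: np.ndarray, starts: np.ndarray,
                  seqs: SequenceSet, width_max: int) -> np.ndarray:
    out = np.empty((len(widths), 2))
    for i in range(len(widths)):
        out[i] = _evaluate(int(widths[i]), starts[i], seqs, width_max)
    return out


def initialize_population(seqs: SequenceSet, config: GAConfig,
                          rng: np.random.Generator) -> Population:
    """Random widths and start positions, uniform over their valid ranges."""
    w_hi = min(config.width_max, seqs.min_length)
    if w_hi < config.width_min:
        raise ValidationError(
            f"shortest sequence ({seqs.min_length} bp) cannot hold a "
            f"width-{config.width_min} motif"
        )
    P = config.population_size
    widths = rng.integers(config.width_min, w_hi + 1, size=P)
    starts = np.empty((P, seqs.N), dtype=np.int64)
    for i in range(P):
        # each start uniform on [0, length - width]
        starts[i] = rng.integers(0, seqs.lengths - widths[i] + 1)
    members = [Candidate(int(widths[i]), tuple(int(s) for s in starts[i]))
               for i in range(P)]
    fits = _evaluate_all(widths, starts, seqs, config.width_max)
    return Population(seqs, members, fits, generation=0)


def niche_count(index: int, population: Population, sigma_share: float) -> int:
    """Members within Chebyshev distance sigma_share of member ``index``.

    Always >= 1: an individual counts itself.
    """
    return _niche_count(population.fitness, index, sigma_share)


def _niche_count(fits: np.ndarray, index: int, sigma_share: float) -> int:
    d = np.abs(fits - fits[index]).max(axis=1)
    return int((d <= sigma_share).sum())


def shared_fitness(f: FitnessVector, q: int) -> FitnessVector:
    """Derate a fitness vector by its niche count: f_s = f / q."""
    if q < 1:
        raise ValidationError("niche count must be >= 1")
    return FitnessVector(f.similarity / q, f.norm_length / q)


def _dominated_by_any(fit: np.ndarray, others: np.ndarray) -> bool:
    """True if any row of ``others`` Pareto-dominates ``fit`` (maximization)."""
    geq = (others >= fit).all(axis=1)
    gt = (others > fit).any(axis=1)
    return bool((geq & gt).any())


def _tournament(ia: int, ib: int, fits: np.ndarray, config: GAConfig,
                rng: np.random.Generator) -> int:
    P = len(fits)
    pool = np.delete(np.arange(P), [ia, ib]) if P > config.t_dom + 2 else None
    if pool is not None:
        comp = rng.choice(pool, size=config.t_dom, replace=False)
    else:
        others = [i for i in range(P) if i not in (ia, ib)]
        comp = np.array(others) if others else np.array([ia, ib])
    comp_fits = fits[comp]
    a_dom = _dominated_by_any(fits[ia], comp_fits)
    b_dom = _dominated_by_any(fits[ib], comp_fits)
    if a_dom != b_dom:
        return ib if a_dom else ia
    qa = _niche_count(fits, ia, config.sigma_share)
    qb = _niche_count(fits, ib, config.sigma_share)
    if qa != qb:
        return ia if qa < qb else ib
    return ia if rng.random() < 0.5 else ib


def pareto_tournament(cand_a: Candidate, cand_b: Candidate,
                      population: Population, config: GAConfig,
                      rng: np.random.Generator) -> Candidate:
    """Pareto domination tournament between two candidates.

    A candidate dominated by no member of the random comparison set wins;
    when neither or both survive, the smaller niche count wins, and a
    residual tie falls to a coin flip.
    """
    if len(population) == 0:
        raise ValidationError("empty population")
    fits = population.fitness
    try:
        ia = population.members.index(cand_a)
        ib = population.members.index(cand_b)
    except ValueError:
        # candidates outside the population: compare against it directly
        fa = population.fitness_of(cand_a)
        fb = population.fitness_of(cand_b)
        fits = np.vstack([fits, fa, fb])
        ia, ib = len(fits) - 2, len(fits) - 1
    winner = _tournament(ia, ib, fits, config, rng)
    return cand_a if winner == ia else cand_b


def one_point_crossover(parent_a: Candidate, parent_b: Candidate,
                        seqs: SequenceSet, rng: np.random.Generator,
                        k: int | None = None) -> tuple[Candidate, Candidate]:
    """Swap start-position tails after a crossover point k in {1, ..., N-1}.

    Each offspring keeps its own parent's width; inherited starts that
    overrun a sequence end are clamped to length - width.
    """
    N = seqs.N
    if N < 2:
        raise ValidationError("crossover needs at least 2 sequences")
    if k is None:
        k = int(rng.integers(1, N))
    if not 1 <= k <= N - 1:
        raise ValidationError(f"crossover point {k} outside [1, {N - 1}]")
    a, b = np.asarray(parent_a.starts), np.asarray(parent_b.starts)
    child_a = np.concatenate([a[:k], b[k:]])
    child_b = np.concatenate([b[:k], a[k:]])
    child_a = np.minimum(child_a, seqs.lengths - parent_a.width)
    child_b = np.minimum(child_b, seqs.lengths - parent_b.width)
    return (
        Candidate(parent_a.width, tuple(int(s) for s in child_a)),
        Candidate(parent_b.width, tuple(int(s) for s in child_b)),
    )


def mutate(candidate: Candidate, seqs: SequenceSet, config: GAConfig,
           rng: np.random.Generator) -> Candidate:
    """Resample one start position and/or shift the width by one base.

    With ``mutation_prob``, a victim sequence index is drawn uniformly and
    its start resampled uniformly on the valid range.  With
    ``width_mutation_prob``, the width moves by +/-1 inside the allowed
    bounds and all starts are re-clamped.
    """
    width = candidate.width
    starts = np.asarray(candidate.starts).copy()
    changed = False
    if rng.random() < config.mutation_prob:
        i = int(rng.integers(seqs.N))
        starts[i] = int(rng.integers(0, int(seqs.lengths[i]) - width + 1))
        changed = True
    if rng.random() < config.width_mutation_prob:
        w_hi = min(config.width_max, seqs.min_length)
        step = -1 if rng.random() < 0.5 else 1
        new_w = min(max(width + step, config.width_min), w_hi)
        if new_w != width:
            width = new_w
            starts = np.minimum(starts, seqs.lengths - width)
            changed = True
    if not changed:
        return candidate
    return Candidate(width, tuple(int(s) for s in starts))


def _best_start(width: int, starts: np.ndarray, seqs: SequenceSet,
                victim: int) -> int:
    """Start in sequence ``victim`` maximizing similarity given the others.

    Scores every window of the victim sequence against the profile of the
    other N-1 sites and returns the argmax (first position on ties).
    """
    mat = site_matrix(width, starts, seqs)
    counts = profile_counts(mat)
    cols = np.arange(width)
    counts[mat[victim], cols] -= 1  # leave the victim's own site out
    windows = sliding_window_view(seqs.encoded[victim], width)
    scores = counts[windows, cols].sum(axis=1)
    return int(np.argmax(scores))


def _refine_pass(width: int, starts: np.ndarray, seqs: SequenceSet,
                 rng: np.random.Generator) -> np.ndarray:
    """One coordinate-ascent sweep: re-place every start, in random order."""
    out = starts.copy()
    for i in rng.permutation(seqs.N):
        out[i] = _best_start(width, out, seqs, int(i))
    return out


def local_refine(candidate: Candidate, seqs: SequenceSet,
                 rng: np.random.Generator) -> Candidate:
    """Greedy local refinement of a candidate's start positions.

    Visits the sequences in random order and moves each start to the
    position whose site best matches the profile of the current other
    sites.  Similarity never decreases; widths are untouched.  This is
    the memetic step that lets the evolutionary search lock a partially
    assembled alignment onto a motif.
    """
    starts = _refine_pass(candidate.width,
                          np.asarray(candidate.starts, dtype=np.int64),
                          seqs, rng)
    return Candidate(candidate.width, tuple(int(s) for s in starts))


def _front_indices(fits: np.ndarray) -> np.ndarray:
    """Indices of members dominated by no other member."""
    P = len(fits)
    keep = np.ones(P, dtype=bool)
    for i in range(P):
        if not keep[i]:
            continue
        geq = (fits >= fits[i]).all(axis=1)
        gt = (fits > fits[i]).any(axis=1)
        if (geq & gt).any():
            keep[i] = False
    return np.flatnonzero(keep)


def pareto_front(population: Population) -> list[Candidate]:
    """Non-dominated members, one candidate per width, sorted by width.

    Two non-dominated members of equal width necessarily tie on both
    objectives; the duplicate with the lexicographically smallest consensus
    is kept, so the result is deterministic.
    """
    idx = _front_indices(population.fitness)
    best: dict[int, tuple[str, Candidate]] = {}
    for i in idx:
        cand = population.members[i]
        mat = site_matrix(cand.width, np.asarray(cand.starts), population.seqs)
        cons = consensus_string(ProfileMatrix(profile_counts(mat)))
        cur = best.get(cand.width)
        if cur is None or cons < cur[0]:
            best[cand.width] = (cons, cand)
    return [best[w][1] for w in sorted(best)]


def evolve(seqs: SequenceSet, config: GAConfig,
           on_generation: Callable[[int, float, np.ndarray], None] | None = None,
           ) -> list[tuple[Candidate, FitnessVector, str]]:
    """Run the full evolutionary loop and return the final Pareto front.

    Each generation: P Pareto tournaments pick parents, adjacent parents
    recombine with ``crossover_prob``, offspring mutate (and with
    ``refine_prob`` receive a local-refinement sweep), and the previous
    non-dominated set is re-inserted over the weakest offspring.  The loop
    stops at ``max_generations`` or when the population mean of
    ``(similarity + norm_length) / 2`` improves by less than
    ``stagnation_eps`` for ``stagnation_generations`` consecutive
    generations.

    Returns ``(candidate, fitness, consensus)`` triples sorted by width.
    ``on_generation(generation, mean_fitness, front_fitness_rows)`` is
    called once per generation when given.
    """
    rng = np.random.default_rng(config.rng_seed)
    pop = initialize_population(seqs, config, rng)
    P = config.population_size
    width_max = config.width_max

    widths = np.array([m.width for m in pop.members], dtype=np.int64)
    starts = np.array([m.starts for m in pop.members], dtype=np.int64)
    fits = pop.fitness

    prev_mean = fits.mean(axis=1).mean()
    stale = 0
    generation = 0
    for generation in range(1, config.max_generations + 1):
        # --- selection: P Pareto domination tournaments
        parents = np.empty(P, dtype=np.int64)
        for s in range(P):
            ia, ib = rng.choice(P, size=2, replace=False)
            parents[s] = _tournament(int(ia), int(ib), fits, config, rng)

        # --- crossover over adjacent parent pairs
        off_w = widths[parents].copy()
        off_s = starts[parents].copy()
        for j in range(0, P - 1, 2):
            if rng.random() < config.crossover_prob:
                k = int(rng.integers(1, seqs.N))
                tail_a = off_s[j, k:].copy()
                off_s[j, k:] = off_s[j + 1, k:]
                off_s[j + 1, k:] = tail_a
                off_s[j] = np.minimum(off_s[j], seqs.lengths - off_w[j])
                off_s[j + 1] = np.minimum(off_s[j + 1], seqs.lengths - off_w[j + 1])

        # --- mutation and local refinement
        w_hi = min(width_max, seqs.min_length)
        for j in range(P):
            if rng.random() < config.mutation_prob:
                i = int(rng.integers(seqs.N))
                off_s[j, i] = rng.integers(0, seqs.lengths[i] - off_w[j] + 1)
            if rng.random() < config.width_mutation_prob:
                step = -1 if rng.random() < 0.5 else 1
                new_w = min(max(int(off_w[j]) + step, config.width_min), w_hi)
                if new_w != off_w[j]:
                    off_w[j] = new_w
                    off_s[j] = np.minimum(off_s[j], seqs.lengths - new_w)
            if rng.random() < config.shift_prob:
                delta = int(rng.integers(1, 3)) * (-1 if rng.random() < 0.5 else 1)
                off_s[j] = np.clip(off_s[j] + delta, 0,
                                   seqs.lengths - off_w[j])
            if rng.random() < config.refine_prob:
                off_s[j] = _refine_pass(int(off_w[j]), off_s[j], seqs, rng)

        off_fits = _evaluate_all(off_w, off_s, seqs, width_max)

        # --- elitist carry-over: previous non-dominated set (one per width)
        # replaces the weakest offspring
        elite_idx = _front_indices(fits)
        per_width: dict[int, int] = {}
        for i in elite_idx:
            w = int(widths[i])
            if w not in per_width:
                per_width[w] = int(i)
        elites = list(per_width.values())[: P - 1]
        order = np.argsort(off_fits.mean(axis=1))  # weakest first
        for slot, i in zip(order, elites):
            off_w[slot] = widths[i]
            off_s[slot] = starts[i]
            off_fits[slot] = fits[i]

        widths, starts, fits = off_w, off_s, off_fits

        mean_fit = fits.mean(axis=1).mean()
        if on_generation is not None:
            on_generation(generation, float(mean_fit), fits[_front_indices(fits)])
        if mean_fit - prev_mean < config.stagnation_eps:
            stale += 1
            if stale >= config.stagnation_generations:
                break
        else:
            stale = 0
        prev_mean = max(prev_mean, mean_fit)

    members = [Candidate(int(widths[i]), tuple(int(s) for s in starts[i]))
               for i in range(P)]
    final = Population(seqs, members, fits, generation=generation)
    result = []
    for cand in pareto_front(final):
        mat = site_matrix(cand.width, np.asarray(cand.starts), seqs)
        counts = profile_counts(mat)
        sim = float(counts.max(axis=0).sum()) / (seqs.N * cand.width)
        fv = FitnessVector(sim, cand.width / width_max)
        result.append((cand, fv, consensus_string(ProfileMatrix(counts))))
    return result
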