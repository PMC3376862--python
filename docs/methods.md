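# Methods

## Model

The search space is the set of candidate motifs `(w, p1, …, pN)` over `N`
input sequences: a motif width `w ∈ [4, 20]` and one 0-based start per
sequence, so exactly one site per sequence (an OOPS-style occurrence
model).  All coordinates are 0-based half-open internally and in BED
output; human-readable reports use 1-based inclusive positions.  Only the
forward strand is modelled; the strand column of every output is `+`.

Two objectives are maximized jointly:

1. **Consensus similarity** `sim = Σⱼ f_max(j) / (N·w)`, with `f_max(j)`
   the largest count in column `j` of the 4×w position frequency matrix of
   the extracted sites.  This is the unique column-maximum normalization
   whose range is (0.25, 1] with 1.0 exactly when all `N` sites are
   identical.  The normalization is inferred from that requirement and
   from the column-maximum definition; treat the precise form as this
   package's reconstruction rather than a literal transcription.
2. **Normalized length** `w / w_max`, `w_max = 20`.

A fitness vector `u` dominates `v` iff `u ≥ v` componentwise with strict
inequality somewhere; equal vectors are mutually non-inferior.  The
consensus string takes each column's most frequent base, ties broken by
the fixed order A < C < G < T for reproducibility.

## The evolutionary engine

Each generation of the niched Pareto GA:

1. **Selection** — `population_size` Pareto domination tournaments.  Two
   distinct members are drawn; a comparison set of `t_dom` members (drawn
   without replacement, excluding the two candidates when the population
   allows) defines domination.  If exactly one candidate is undominated by
   the whole set it wins; otherwise the smaller niche count wins, and a
   residual tie falls to a coin flip.  The niche count of a member is the
   number of members within Chebyshev distance `sigma_share` of its
   fitness vector — Chebyshev because both objectives are already on
   [0, 1] scales; the shared fitness itself is `f_s = f / q`.
2. **Crossover** (`crossover_prob = 0.8`) — one-point crossover over the
   N-element start vector, point uniform on {1, …, N−1}; each offspring
   keeps its own parent's width, and inherited starts are clamped to
   `length − width`.  (A crossover point "inside the motif" is not
   meaningful for a position-vector chromosome; the point is taken over
   the start vector, as in the GALF/GAME representation lineage.)
3. **Mutation** (`mutation_prob = 0.2`) — one victim sequence index,
   start resampled uniformly on its valid range.  **Width drift**
   (`width_mutation_prob = 0.1`) moves the width ±1 within bounds so
   lengths can adapt after initialization.  **Shift**
   (`shift_prob = 0.1`) slides all starts together by ±1–2 bases:
   coordinate-wise moves cannot escape phase-shifted optima (any single
   site moved first lowers similarity), the coordinated slide can.
4. **Local refinement** (`refine_prob = 0.2`) — one coordinate-ascent
   sweep: in random order, each start is re-placed at the window of its
   sequence best matching the profile of the other N−1 sites.  Similarity
   never decreases.  This memetic step is what lets partially assembled
   alignments lock onto a motif at realistic population sizes; with the
   paper-literal operator set alone (`refine_prob = shift_prob =
   width_mutation_prob = 0`), recovery of even an easy planted motif is
   near zero at population 100.
5. **Replacement** — generational, with elitist carry-over: the current
   non-dominated set (one member per width) replaces the weakest offspring
   (by mean of the two objectives).  Elitism guarantees the front at
   generation g+1 is never dominated by the front at generation g.

**Stopping.**  The run stops at `max_generations = 200` or when the
population mean of `(sim + norm_length)/2` fails to improve on its
best-so-far value by at least `stagnation_eps = 1e-4` for 10 consecutive
generations.  The mean-of-scalarized choice is one of several reasonable
readings of "average fitness" for a vector-valued objective; comparing
against best-so-far rather than the previous generation prevents
oscillations from deferring the stop indefinitely.  The default epsilon is
deliberately small: at 1e-3 the population mean plateaus (a property of
niched selection, which holds the population spread across the front)
while the elites are still improving, and runs terminate mid-convergence.

**Output.**  The final front: all non-dominated members, deduplicated to
one candidate per width (two non-dominated members of equal width
necessarily tie on both objectives; the lexicographically smallest
consensus is kept), sorted by width.  One motif per length is an inherent
property of this representation — of several same-length motifs only the
best-conserved can survive.

Fixing `rng_seed` fixes the entire run bit for bit; all randomness flows
from one generator.

## Synthetic benchmark

`ScenarioSpec` fixes the number of sequences (8–20), sequence length
(200–500 bp), background composition and the planted motifs.  Backgrounds
are i.i.d.: uniform (each base 0.25), AT-rich (A = T = 0.30,
C = G = 0.20) or GC-rich (mirrored); the published recipe fixes only the
60/40 pair totals, the equal split within each pair is this package's
choice.  Each motif instance is drawn column-wise from its conservation
profile — consensus base 0.91 / others 0.03 (high), or 0.70 / 0.10 (low) —
and overwrites the background at a uniform position, rejection-sampled so
sites within one sequence never overlap; overwriting (rather than
inserting) keeps sequence lengths exactly as specified.  One instance of
every motif is planted in every sequence, matching the one-site-per-
sequence model the engine assumes.  Consensus strings are drawn uniformly
at random per replicate unless given explicitly.

What the generator does **not** emulate: real promoters have correlated,
repeat-laden backgrounds, motif instances occur zero or multiple times per
sequence, site lengths vary, and both strands carry sites.  Passing these
benchmarks therefore demonstrates correct optimization of the stated
objective under its own generative assumptions, not performance on
genomic data.

## Evaluation

Site-level matching is a necessary convention on top of the published
precision/recall definitions (which never state when a predicted site
"is" a true site): a pair is eligible when the overlap is at least
`min_overlap_fraction = 0.5` of the shorter site's width; eligible pairs
are matched greedily by decreasing overlap, one-to-one per sequence.
For multi-motif datasets, discovered front members are assigned to
planted motifs by solving the small linear-assignment problem maximizing
total F (scipy's Hungarian solver); each planted motif is then scored by
its assigned discovered motif, or 0 if none.  `F = 2PR/(P+R)`, defined as
0 when `P + R = 0`.  Consensus-identity success uses the best ungapped
offset of the shorter consensus inside the longer, succeeding above 70%
identity.

## Problem sizes used in tests and the acceptance script

The recovery experiments run the engine at its defaults (population 100,
≤ 200 generations, stopping early on stagnation) on three scenario
recipes, 10 independently seeded replicates each: 8 × 200 bp with one
high-conservation width-8 motif; 16 × 500 bp with three motifs (6 high,
12 low, 15 high); 12 × 300 bp with two motifs (7 high, 11 low).  Each
replicate redraws consensus strings, dataset and GA seed from the
replicate index, so the replicates are independent repetitions of the
same recipe.

## Known limitations

- **Low-conservation motifs co-planted with high-conservation ones are
  usually not reported.**  This is a property of the objective, not of
  the search: a width-11 window that covers a co-planted width-7
  high-conservation motif scores `(7·0.91·N + 4·E[background column
  max])/(11N)` ≈ 0.75, while the true width-11 low-conservation alignment
  scores ≈ 0.70.  Multistart coordinate ascent confirms the deceptive
  window wins at width 11 in essentially every replicate of the 12 × 300
  scenario, so the true low motif is strictly dominated and excluded from
  the non-dominated front by definition.  It surfaces only in replicates
  whose conservation draw is unusually tight.  Low-conservation motifs
  *alone* in a dataset fare better but remain near the detection limit of
  the similarity score at these sequence lengths, where optimized
  background alignments reach comparable scores.
- Short widths (4–6) on the front are usually background artifacts:
  near-perfect 4-mer alignments exist by chance in any dataset of this
  size.  Judge front members jointly with their length, as the
  two-objective formulation intends.
- The engine evaluates ~`population_size` candidates per generation with
  an O(N·w) profile tally each; runtime grows linearly in sequence count
  and length through the refinement sweep (O(N·L·w) per sweep).  The
  benchmark scenarios above run in roughly 1–3 s per replicate.
- The comparison set of a tournament excludes the two competing
  candidates when the population is large enough; whether the original
  scheme does so is unspecified.
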