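# Methods

## The optimization problem

`molfinder` searches chemical space for molecules that maximize a
user-chosen property objective.  Molecules are represented as SMILES
strings throughout: the genetic operators act on the string (or, for
substitution, on the molecular graph parsed from it), which makes the
search independent of any trained generative model and cheap to run on a
single CPU.

## Conformational space annealing

The search is a conformational space annealing (CSA) loop, an
evolutionary algorithm whose selection step explicitly controls the
diversity of the population:

* **Bank.** A fixed-size set of `n_bank` molecules (default 1000; no two
  members share a canonical SMILES).  The initial bank is a uniform draw
  from the seed pool.  Its mean pairwise distance `d_avg` — distance is
  `1 − Tanimoto` on 2048-bit topological path fingerprints — is computed
  once at initialization and sets the annealing scale.
* **Seeds.** Each generation the `n_seed` best members (default 600, ties
  broken lexicographically on SMILES) each spawn a batch of children:
  40 by crossover (each with a fresh random partner drawn from the whole
  bank) and 20 by each of insertion, deletion and substitution, i.e. up
  to 100 children per seed, deduplicated within the batch.
* **Update rule.** Children are scored and applied to the bank
  sequentially.  A child worse than (or equal to) the current worst
  member is discarded.  Otherwise its nearest bank neighbor is found:
  closer than `d_cut` means "same basin" and the child replaces that
  neighbor only if strictly better (a duplicate SMILES always keeps the
  incumbent); farther than `d_cut` means a new basin and the child
  replaces the current worst member.  Bank size is invariant under every
  branch, so the best and worst bank objectives are monotonically
  non-decreasing.
* **Annealing.** `d_cut` starts at `d_avg/2` and after every generation
  is set to `max(d_avg/2 · 0.98^g, d_avg/5)`.  The schedule is a closed
  form of the generation index rather than a running product, so the
  trajectory satisfies it exactly in floating point.  Early generations
  therefore insist on diverse basins; late generations allow fine local
  refinement.
* **Local optimization (optional).** With `local_opt` enabled, each child
  is hill-climbed by up to `local_opt_trials` (default 10) valence-aware
  substitutions, accepting only strict improvements.

Termination is by `max_generations` plus an optional `patience` on
best-objective stagnation; both are configuration choices since the
algorithm itself has no natural stopping point.

## SMILES genetic operators

Random string edits on SMILES mostly produce syntax errors, so each
operator embeds targeted repairs; the toolkit sanitizer always has the
final word, and every operator retries with fresh random choices up to a
budget (30 per orientation) before giving up and returning `None`.

* **Crossover.** One parent keeps a left prefix, the other a right
  suffix, and the halves are concatenated.  Cut points are drawn
  uniformly from the *admissible set*: token boundaries (never inside a
  bracket atom, `Cl`/`Br`, or a `%nn` ring label) at which no ring-bond
  digit pair is severed, so rings always travel whole.  After
  concatenation, unbalanced branch parentheses are repaired — excess
  closers deleted uniformly at random, missing closers inserted at
  random positions after the first atom where the nesting depth is
  positive.  30 attempts with fresh cuts, then the parents swap roles
  for 30 more; the pair is discarded after 60 failures.
* **Insertion / deletion.** One atom token from the alphabet
  C, N, O, S, P, F, Cl, Br, I is inserted at a random token boundary
  (spelled lowercase when flanked by aromatic atoms), or one atom token
  is removed.  A valid child changes the heavy-atom count by exactly ±1.
* **Substitution.** Operates on the parsed graph: a random uncharged atom
  is rewritten to a different alphabet element whose maximum valence
  (C 4, N 3, O 2, S 6, P 5, halogens 1) covers the atom's explicit
  valence; aromatic positions only accept aromatic-capable elements.
  Heavy-atom count and bond topology are preserved.

Stereochemistry and formal charges present in the input survive where
the edit does not touch them; the operators never introduce new ones.
Bond-order mutation and ring-forming graph edits are deliberately out of
scope.

Measured on the embedded drug-like fixture set, the mutation operators
(with retries) succeed for well over 99% of calls.  The crossover
protocol succeeds for essentially every parent pair, because with cut
points resampled on each of the 60 attempts even a per-concatenation
validity around 50% leaves a vanishing chance of 60 consecutive
failures; the per-pair failure mode requires structurally incompatible
parents.  `scripts/acceptance.py` recomputes both rates from scratch.

## Objectives

All objectives are maximized.  QED (drug-likeness in [0, 1]) and the
Ertl synthetic-accessibility score SA (≈1 easy … 10 hard) come from the
cheminformatics toolkit and are cached per canonical SMILES.

* `mqed`: `w·QED − (1−w)·SA`, default `w = 0.994`.  SA enters raw.
* `normalized_mqed`: `w·QED + (1−w)·(1 − (SA−1)/9)`, mapping into
  [0, 1].  SA is clamped to [1, 10] first because the Ertl estimate can
  marginally overshoot its nominal range; the unnormalized form is left
  unclamped since it presumes no range.
* `similarity_qed`: `w·sim + (1−w)·QED` with `sim` the Tanimoto
  similarity of 2048-bit radius-2 Morgan fingerprints to a reference
  molecule, default `w = 0.8`.
* Custom objectives are arbitrary callables on a scored record,
  registered by name for CLI use.

Fingerprint parameters (2048 bits, Morgan radius 2, 166-bit MACCS keys
for analysis) are the toolkit defaults for the cited usages.  The
empty-fingerprint edge case defines Tanimoto(∅, ∅) = 1 so a molecule is
always at distance 0 from itself, and ∅ versus non-empty as 0.

## Seed fixtures

Real screening-library downloads are deliberately not required.  Two
embedded sources stand in for a random sample of a purchasable
drug-like library:

* a static list of ~200 named public-domain drug structures, used as
  realistic strings for operator validity measurements;
* a deterministic generator that assembles molecules by grafting
  fragments — a ring-system table (azoles, azines, saturated N/O
  heterocycles, carbocycles, fused bicyclics), short linkers and
  terminal substituents — joined by single bonds at open-valence atoms,
  constrained to a requested heavy-atom range (default 15–35, matching
  drug-like molecular weights) and ring count (default 1–4).

The generated sets are unique, valid, canonical, reproducible under the
RNG seed, and give a nondegenerate initial `d_avg`.  They emulate the
size and ring statistics of drug-like libraries but not their full
property distributions (no stereochemistry, no charged protonation
states, simpler substitution patterns).  Passing tests on these sets
demonstrates the mechanics of the algorithm, not performance on any
specific vendor library; absolute objective values reached will differ
on real seed sets.

## Problem sizes used in tests and the acceptance script

The published configuration (bank 1000, 600 seeds, 100 children per
seed, runs of many hundred generations) is a day-scale computation.  The
test suite exercises the identical code paths at reduced sizes chosen as
the package's standard desk-scale checks: a bank of 100 with 60 seeds
per generation, 4 crossover + 3×2 mutation children per seed, and 50
generations; operator validity rates are measured over 10,000 attempts.
The diversity ablation pins `d_cut = 0` (`dcut_override`), which reduces
the update rule to greedy elitism and demonstrably yields a more
self-similar final bank than the annealed run under identical seeding.

## Numerical and design choices

* Identity is canonical-SMILES string equality everywhere (dedup,
  novelty, bank membership) — deterministic and independent of
  fingerprint collisions.
* Ties: seed selection and top-k break objective ties lexicographically
  on SMILES; the worst-member eviction breaks value ties by evicting the
  lexicographically largest SMILES; a same-basin tie keeps the
  incumbent.  All choices are for run-to-run stability.
* `d_avg` is never recomputed after initialization; the schedule is
  anchored to the first bank.
* Every stochastic component draws from one NumPy generator seeded by
  `rng_seed`; identical configuration and seeds give byte-identical
  result files.
* Acyclic molecules have an empty Murcko framework and are counted as a
  single sentinel scaffold class in reports.

## Known limitations

* No bond-order mutation: objectives rewarding specific unsaturation
  patterns (e.g. some multi-property tasks) are harder to reach.
* The string-level crossover can shift large substituents between
  scaffolds but cannot recombine inside a ring system.
* QED is degenerate near its optimum — many distinct molecules share
  near-maximal scores — so the diversity rule, not the objective,
  carries the burden of spreading the bank.
* Operator validity rates depend on the molecule set; sets rich in
  bracket atoms, charges and stereocenters will fail more often than
  the embedded fixtures.
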