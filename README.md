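# molfinder

Global optimization of molecular properties by an evolutionary search on
SMILES strings, with explicit diversity control.

`molfinder` is for computational chemists who want to find novel,
synthesizable, drug-like molecules (or molecules similar to a reference
compound) without training a generative model: the search needs nothing
but a seed collection of SMILES strings and a single CPU.

## The algorithm

The engine is a conformational space annealing (CSA) loop. It maintains a
fixed-size *bank* of `N_bank` molecules. Each generation the `N_seed`
best members each spawn up to 100 children — 40 by ring-aware crossover
of SMILES strings (with a random partner from the whole bank) and 20 by
each of atom insertion, deletion and valence-aware substitution. A child
`m` competes for a bank slot under a distance rule with cutoff `D_cut`,
where the distance between molecules is `1 − T(m_i, m_j)` (Tanimoto
coefficient of topological path fingerprints):

* worse than the current worst bank member → discarded;
* nearest bank neighbor closer than `D_cut` → same basin: replaces that
  neighbor only if better;
* all neighbors farther than `D_cut` → new basin: replaces the worst
  member.

`D_cut` starts at half the initial bank's average pairwise distance
`D_avg` and decays by a factor 0.98 per generation to a floor of
`D_avg/5` — broad exploration first, local refinement later.

Built-in objectives (all maximized; QED = quantitative estimate of
drug-likeness, SA = Ertl synthetic-accessibility score):

* `mqed`   S = w·QED − (1−w)·SA        (default w = 0.994)
* `nmqed`  S = w·QED + (1−w)·(1 − (SA−1)/9)
* `simqed` S = w·T_Morgan(m, m_ref) + (1−w)·QED   (default w = 0.8)

plus a registry for custom objective callables.

## Worked example

```bash
molfinder gen-seeds --n 120 --rng-seed 1 --out seeds.smi
molfinder run --seeds seeds.smi --objective mqed \
    --nbank 100 --nseed 60 --crossover-children 4 --mutation-children 2 \
    --generations 10 --rng-seed 1 --out run1
```

The run log prints one line per generation:

```
gen    8  best 0.9262  mean 0.9053  worst 0.8967  d_cut 0.3136
gen    9  best 0.9262  mean 0.9068  worst 0.8988  d_cut 0.3073
gen   10  best 0.9262  mean 0.9090  worst 0.9014  d_cut 0.3012
best: COc1cccc2c(N3CCN(C4CC4)CC3)c(O)ccc12 (0.9262)
```

`best/mean/worst` are bank objective values (here penalized
drug-likeness: the whole bank climbs from a seed mean of 0.61 to 0.91
while `d_cut` anneals down), and the best molecule found is a
methoxy/hydroxy-naphthalene with a cyclopropyl-piperazine — QED 0.945,
SA 2.20, i.e. highly drug-like and easy to synthesize. `run1/` contains
`final_bank.csv` (one scored row per bank member), `trajectory.csv` and
a `manifest.json` echoing the configuration and operator statistics.

Diversity/novelty analysis of the result against the seed set:

```bash
molfinder analyze --results run1/final_bank.csv --reference seeds.smi
```

```json
{
  "n_total": 100, "n_unique": 100, "n_novel": 100,
  "n_scaffolds": 91, "p_scaffolds": 0.91, "pct_novel_scaffolds": 97.8,
  "sim_mean": 0.272, "sim_std": 0.067
}
```

Every bank member is unique and absent from the seed set; the 100
molecules span 91 distinct Bemis–Murcko scaffolds, almost all unseen in
the seeds, and the mean pairwise similarity of 0.27 shows the bank has
not collapsed onto one chemotype.

## Layout

* `src/molfinder/molecule.py` — canonical SMILES, fingerprints,
  Tanimoto distance, Murcko scaffolds
* `src/molfinder/variation.py` — crossover and mutation operators
* `src/molfinder/objectives.py` — objective functions and plug-in registry
* `src/molfinder/engine.py` — the CSA search loop
* `src/molfinder/analysis.py` — diversity / novelty / scaffold reports
* `src/molfinder/fixtures.py` — embedded drug list and seed generator
* `src/molfinder/cli.py`, `io.py` — command line and file formats

See `docs/methods.md` for the full model description, parameter
defaults and known limitations.
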