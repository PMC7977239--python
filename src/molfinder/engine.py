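"""The conformational space annealing (CSA) search loop.

CSA keeps a fixed-size *bank* of candidate molecules.  Each generation the
best ``n_seed`` bank members each spawn a batch of children by crossover
and mutation; children compete for bank slots under a diversity rule
governed by an annealed distance cutoff ``d_cut``:

* a child worse than the current worst bank member is discarded;
* a child closer than ``d_cut`` to its nearest bank neighbor is treated
  as being in the same basin and replaces that neighbor only if better;
* a child farther than ``d_cut`` from every bank member opens a new basin
  and replaces the current worst member.

``d_cut`` starts at half the initial bank's mean pairwise distance and
decays by a factor of 0.98 per generation down to a floor of one fifth of
that mean, shifting the search from broad exploration to local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import DataStructs

from .errors import ConfigError, InsufficientSeeds
from .molecule import FP_RDKIT, MoleculeRecord, safe_canonical
from .objectives import ObjectiveSpec, score
from .variation import OperatorStats, generate_children, substitute_atom


@dataclass
class RunConfig:
    """All hyperparameters of one CSA run."""

    n_bank: int = 1000
    n_seed: int = 600
    n_crossover_children: int = 40
    n_children_per_mutation: int = 20
    crossover_tries: int = 30   # per orientation; role swap doubles it
    mutation_tries: int = 30
    dcut_decay: float = 0.98
    dcut_floor_divisor: float = 5.0
    #: pin d_cut to a fixed value (ablation hook; 0 disables the
    #: same-basin rule entirely, giving a greedy elitist update)
    dcut_override: Optional[float] = None
    local_opt: bool = False
    local_opt_trials: int = 10
    max_generations: int = 100
    patience: Optional[int] = None
    rng_seed: int = 0
    objective: ObjectiveSpec = field(default_factory=ObjectiveSpec)

    def validate(self) -> None:
        if self.n_seed > self.n_bank:
            raise ConfigError("n_seed must not exceed n_bank")
        if not 0.0 < self.dcut_decay < 1.0:
            raise ConfigError("dcut_decay must lie in (0, 1)")
        if self.dcut_floor_divisor < 2.0:
            raise ConfigError("dcut_floor_divisor must be >= 2 (floor <= d_avg/2)")
        if self.n_bank < 2 or self.max_generations < 1:
            raise ConfigError("n_bank >= 2 and max_generations >= 1 required")


@dataclass
class Bank:
    """The fixed-size population plus the annealing state."""

    records: list[MoleculeRecord]
    d_avg: float
    d_cut: float
    generation: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def smiles_set(self) -> set[str]:
        return {r.canonical_smiles for r in self.records}

    def objectives(self) -> np.ndarray:
        return np.array([r.objective_value for r in self.records])

    def worst_index(self) -> int:
        objs = self.objectives()
        # deterministic tie-break: lexicographically larger SMILES goes first
        worst = np.flatnonzero(objs == objs.min())
        if len(worst) == 1:
            return int(worst[0])
        return max(worst, key=lambda i: self.records[i].canonical_smiles)

    def best(self) -> MoleculeRecord:
        return max(self.records, key=lambda r: (r.objective_value, r.canonical_smiles))


@dataclass
class RunResult:
    """Final bank, per-generation trajectory and the all-time best record."""

    final_bank: Bank
    trajectory: list[dict]
    all_time_best: MoleculeRecord
    operator_stats: dict[str, OperatorStats]


def mean_pairwise_distance(records: list[MoleculeRecord]) -> float:
    """Mean of all n(n-1)/2 pairwise engine distances."""
    fps = [r.fingerprint(FP_RDKIT).bits for r in records]
    n = len(fps)
    total = 0.0
    count = 0
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        total += sum(1.0 - s for s in sims)
        count += i
    return total / count if count else 0.0


def init_bank(seeds: list[str], config: RunConfig, rng: np.random.Generator) -> Bank:
    """Build the initial bank from a seed pool.

    Seeds are canonicalized and deduplicated; ``n_bank`` of them are drawn
    uniformly without replacement, scored, and the mean pairwise distance
    of the draw sets the annealing scale: ``d_cut`` starts at ``d_avg/2``.
    """
    unique: list[str] = []
    seen: set[str] = set()
    for s in seeds:
        c = safe_canonical(s)
        if c is None:
            continue
        if c not in seen:
            seen.add(c)
            unique.append(c)
    if len(unique) < config.n_bank:
        raise InsufficientSeeds(
            f"need {config.n_bank} unique valid seeds, got {len(unique)}"
        )
    chosen = [unique[i] for i in rng.choice(len(unique), size=config.n_bank, replace=False)]
    records = [score(s, config.objective, generation_born=0) for s in chosen]
    d_avg = mean_pairwise_distance(records)
    d_cut = dcut_schedule(d_avg, 0, config)
    return Bank(records=records, d_avg=d_avg, d_cut=d_cut, generation=0)


def dcut_schedule(d_avg: float, generation: int, config: RunConfig) -> float:
    """Annealed cutoff: ``max(d_avg/2 * decay**generation, d_avg/floor_divisor)``."""
    if config.dcut_override is not None:
        return config.dcut_override
    return max(
        d_avg / 2.0 * config.dcut_decay**generation,
        d_avg / config.dcut_floor_divisor,
    )


def select_seeds(bank: Bank, n_seed: int) -> list[MoleculeRecord]:
    """The ``n_seed`` records with the highest objective values.

    Ties are broken by canonical SMILES lexicographic order so selection
    is deterministic.
    """
    if n_seed > len(bank):
        raise ConfigError("n_seed exceeds bank size")
    ordered = sorted(
        bank.records, key=lambda r: (-r.objective_value, r.canonical_smiles)
    )
    return ordered[:n_seed]


def local_optimize(
    mol: MoleculeRecord,
    spec: ObjectiveSpec,
    n_trials: int,
    rng: np.random.Generator,
) -> MoleculeRecord:
    """Hill-climb a molecule by repeated valence-aware atom substitution.

    Each trial proposes one substitution and keeps it only if the
    objective strictly improves, so the returned record is never worse
    than the input.
    """
    current = mol
    for _ in range(n_trials):
        proposal = substitute_atom(current.canonical_smiles, rng)
        if proposal is None:
            continue
        candidate = score(proposal, spec, generation_born=current.generation_born)
        if candidate.objective_value > current.objective_value:
            current = candidate
    return current


def update_bank(bank: Bank, candidate: MoleculeRecord) -> Bank:
    """Apply the three-branch CSA bank-update rule for one candidate.

    Mutates and returns the bank; its size never changes.  A candidate
    already present in the bank (distance zero to itself) falls under the
    same-basin branch with the incumbent kept on ties.
    """
    objs = bank.objectives()
    worst_value = objs.min()
    if candidate.objective_value <= worst_value:
        return bank

    cand_fp = candidate.fingerprint(FP_RDKIT).bits
    sims = DataStructs.BulkTanimotoSimilarity(
        cand_fp, [r.fingerprint(FP_RDKIT).bits for r in bank.records]
    )
    distances = 1.0 - np.asarray(sims)
    nearest = int(np.argmin(distances))

    if distances[nearest] < bank.d_cut or candidate.canonical_smiles in bank.smiles_set():
        # same basin: keep the better of candidate and nearest neighbor
        if candidate.objective_value > bank.records[nearest].objective_value:
            if candidate.canonical_smiles not in bank.smiles_set():
                bank.records[nearest] = candidate
        return bank

    # new basin: candidate evicts the current worst member
    bank.records[bank.worst_index()] = candidate
    return bank


def run(seeds: list[str], config: RunConfig) -> RunResult:
    """Execute a full CSA search and return the final bank and trajectory."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    bank = init_bank(seeds, config, rng)

    stats = {k: OperatorStats() for k in ("crossover", "insert", "delete", "substitute")}
    trajectory: list[dict] = []
    best = bank.best()
    stagnation = 0

    def log_generation() -> None:
        objs = bank.objectives()
        trajectory.append(
            {
                "generation": bank.generation,
                "bank_size": len(bank),
                "best": float(objs.max()),
                "mean": float(objs.mean()),
                "worst": float(objs.min()),
                "d_cut": bank.d_cut,
                "crossover_valid": stats["crossover"].valid,
                "crossover_attempts": stats["crossover"].attempts,
                "mutation_valid": sum(stats[k].valid for k in ("insert", "delete", "substitute")),
                "mutation_attempts": sum(stats[k].attempts for k in ("insert", "delete", "substitute")),
            }
        )

    log_generation()
    for _ in range(config.max_generations):
        seeds_now = select_seeds(bank, config.n_seed)
        for seed in seeds_now:
            children = generate_children(
                seed,
                bank.records,
                rng,
                n_crossover=config.n_crossover_children,
                n_per_mutation=config.n_children_per_mutation,
                crossover_tries=config.crossover_tries,
                mutation_tries=config.mutation_tries,
                stats=stats,
            )
            for child in children:
                record = score(child, config.objective, generation_born=bank.generation + 1)
                if config.local_opt:
                    record = local_optimize(
                        record, config.objective, config.local_opt_trials, rng
                    )
                bank = update_bank(bank, record)
        bank.generation += 1
        bank.d_cut = dcut_schedule(bank.d_avg, bank.generation, config)
        current_best = bank.best()
        if current_best.objective_value > best.objective_value:
            best = current_best
            stagnation = 0
        else:
            stagnation += 1
        log_generation()
        if config.patience is not None and stagnation >= config.patience:
            break

    return RunResult(
        final_bank=bank, trajectory=trajectory, all_time_best=best, operator_stats=stats
    )
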