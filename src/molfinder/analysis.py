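"""Post-run evaluation: diversity, uniqueness, novelty, scaffold statistics.

Mirrors the standard battery for generative molecular optimizers: top-k
extraction by objective, pairwise Tanimoto similarity statistics of the
generated set, the fraction of generated molecules that are unique and
absent from the seed database, and Bemis–Murcko scaffold counts with the
fraction of scaffolds unseen in the seed database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import DataStructs

from .errors import NotEnoughRecords, TooFew
from .molecule import FP_RDKIT, MoleculeRecord, canonicalize, murcko_scaffold

#: Sentinel scaffold class for acyclic molecules (empty Murcko framework).
ACYCLIC_SCAFFOLD = "<acyclic>"

DEFAULT_HISTOGRAM_BINS = 50


def top_k(records: Sequence[MoleculeRecord], k: int) -> list[MoleculeRecord]:
    """The ``k`` highest-objective unique records, best first.

    Duplicate canonical SMILES collapse (first occurrence kept) before
    ranking; ties break lexicographically on SMILES.
    """
    seen: set[str] = set()
    unique = []
    for r in records:
        if r.canonical_smiles not in seen:
            seen.add(r.canonical_smiles)
            unique.append(r)
    if k > len(unique):
        raise NotEnoughRecords(f"asked for top {k} of {len(unique)} unique records")
    unique.sort(key=lambda r: (-r.objective_value, r.canonical_smiles))
    return unique[:k]


def pairwise_similarity_stats(
    mols: Sequence[MoleculeRecord], bins: int = DEFAULT_HISTOGRAM_BINS
) -> tuple[float, float, np.ndarray]:
    """Mean, std and histogram of all pairwise Tanimoto similarities.

    Uses the topological path fingerprint over all n(n-1)/2 unordered
    pairs; the histogram has ``bins`` equal-width bins on [0, 1].
    """
    if len(mols) < 2:
        raise TooFew("need at least two molecules for pairwise statistics")
    fps = [m.fingerprint(FP_RDKIT).bits for m in mols]
    sims: list[float] = []
    for i in range(1, len(fps)):
        sims.extend(DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i]))
    arr = np.asarray(sims)
    hist, _ = np.histogram(arr, bins=bins, range=(0.0, 1.0))
    return float(arr.mean()), float(arr.std()), hist


def novelty(generated: Iterable[str], reference_db: set[str]) -> tuple[int, int]:
    """(n_unique, n_novel): distinct generated SMILES and those not in the db.

    Both sides are assumed canonical; identity is string equality.
    """
    unique = set(generated)
    return len(unique), len(unique - set(reference_db))


@dataclass
class DiversityReport:
    """Aggregate diversity/novelty metrics of one generated set."""

    n_total: int
    n_unique: int
    n_novel: int
    n_scaffolds: int
    p_scaffolds: float
    pct_novel_scaffolds: float
    sim_mean: Optional[float] = None
    sim_std: Optional[float] = None
    sim_histogram: Optional[np.ndarray] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_unique": self.n_unique,
            "n_novel": self.n_novel,
            "n_scaffolds": self.n_scaffolds,
            "p_scaffolds": self.p_scaffolds,
            "pct_novel_scaffolds": self.pct_novel_scaffolds,
            "sim_mean": self.sim_mean,
            "sim_std": self.sim_std,
        }
        if self.sim_histogram is not None:
            d["sim_histogram"] = self.sim_histogram.tolist()
        return d


def _scaffold_class(smiles: str) -> str:
    s = murcko_scaffold(smiles)
    return s if s else ACYCLIC_SCAFFOLD


def scaffold_report(
    generated: Sequence[str],
    reference_db: Iterable[str],
    records: Optional[Sequence[MoleculeRecord]] = None,
) -> DiversityReport:
    """Uniqueness, novelty and scaffold statistics of a generated set.

    ``p_scaffolds`` is the number of distinct Bemis–Murcko scaffolds among
    the *novel* generated molecules divided by the number of novel
    molecules; ``pct_novel_scaffolds`` is the percentage of those
    scaffolds absent from the reference database's scaffold set.  Passing
    the scored ``records`` adds pairwise-similarity statistics.
    """
    generated = [canonicalize(s) for s in generated]
    reference = {canonicalize(s) for s in reference_db}
    unique = list(dict.fromkeys(generated))
    novel = [s for s in unique if s not in reference]

    gen_scaffolds = {_scaffold_class(s) for s in novel}
    ref_scaffolds = {_scaffold_class(s) for s in reference}
    novel_scaffolds = gen_scaffolds - ref_scaffolds

    n_scaffolds = len(gen_scaffolds)
    p_scaffolds = n_scaffolds / len(novel) if novel else 0.0
    pct_novel = 100.0 * len(novel_scaffolds) / n_scaffolds if n_scaffolds else 0.0

    sim_mean = sim_std = None
    hist = None
    if records is not None and len(records) >= 2:
        sim_mean, sim_std, hist = pairwise_similarity_stats(records)

    return DiversityReport(
        n_total=len(generated),
        n_unique=len(unique),
        n_novel=len(novel),
        n_scaffolds=n_scaffolds,
        p_scaffolds=p_scaffolds,
        pct_novel_scaffolds=pct_novel,
        sim_mean=sim_mean,
        sim_std=sim_std,
        sim_histogram=hist,
    )
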