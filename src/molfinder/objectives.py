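"""Objective functions: drug-likeness scores and the similarity-guided objective.

Three built-in objectives are provided, all maximized:

* ``mqed`` — a synthesis-penalized drug-likeness score,
  ``w * QED - (1 - w) * SA``, default ``w = 0.994``;
* ``normalized_mqed`` — the same trade-off with the synthetic-accessibility
  term rescaled onto [0, 1], ``w * QED + (1 - w) * (1 - (SA - 1) / 9)``;
* ``similarity_qed`` — ``w * sim + (1 - w) * QED`` where ``sim`` is the
  Morgan-fingerprint Tanimoto similarity to a reference molecule,
  default ``w = 0.8``.

QED (quantitative estimate of drug-likeness, in [0, 1]) and the Ertl
synthetic-accessibility score (roughly 1 = easy to 10 = hard) are consumed
from the cheminformatics toolkit.  Custom objectives plug in as callables
on a :class:`~molfinder.molecule.MoleculeRecord`.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional

from rdkit import RDConfig
from rdkit.Chem import QED

from .errors import DomainError, MissingReference
from .molecule import (
    FP_MORGAN,
    MoleculeRecord,
    canonicalize,
    mol_from_smiles,
    tanimoto,
)

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (toolkit contrib module)

DEFAULT_W_MQED = 0.994
DEFAULT_W_SIMILARITY = 0.8

#: Registry of named custom objectives (name -> callable(record) -> float).
CUSTOM_OBJECTIVES: dict[str, Callable[[MoleculeRecord], float]] = {}


def register_objective(name: str, fn: Callable[[MoleculeRecord], float]) -> None:
    """Register a custom objective under a CLI-addressable name."""
    CUSTOM_OBJECTIVES[name] = fn


def _check_weight(w: float) -> None:
    if not 0.0 <= w <= 1.0:
        raise DomainError(f"weight must lie in [0, 1], got {w}")


def mqed(qed: float, sa: float, w: float = DEFAULT_W_MQED) -> float:
    """Synthesis-penalized drug-likeness: ``w*qed - (1-w)*sa``."""
    _check_weight(w)
    return w * qed - (1.0 - w) * sa


def normalized_mqed(qed: float, sa: float, w: float = DEFAULT_W_MQED) -> float:
    """Normalized form mapping (qed, sa) in [0,1] x [1,10] into [0,1].

    ``w*qed + (1-w)*(1 - (sa-1)/9)``; the synthetic-accessibility score is
    clamped to [1, 10] first since the Ertl estimate can marginally
    overshoot its nominal range.
    """
    _check_weight(w)
    sa = min(max(sa, 1.0), 10.0)
    return w * qed + (1.0 - w) * (1.0 - (sa - 1.0) / 9.0)


@lru_cache(maxsize=200_000)
def qed_sa(canonical_smiles: str) -> tuple[float, float]:
    """QED and Ertl synthetic-accessibility scores of a molecule, cached."""
    mol = mol_from_smiles(canonical_smiles)
    return QED.qed(mol), sascorer.calculateScore(mol)


@dataclass
class ObjectiveSpec:
    """Which objective to optimize, its weight and optional reference.

    ``kind`` is one of ``mqed``, ``normalized_mqed``, ``similarity_qed``
    or ``custom``.  A similarity objective requires ``reference``; a custom
    one requires ``custom_fn``.
    """

    kind: str = "mqed"
    w: Optional[float] = None
    reference: Optional[str] = None
    custom_fn: Optional[Callable[[MoleculeRecord], float]] = None

    def __post_init__(self) -> None:
        kinds = ("mqed", "normalized_mqed", "similarity_qed", "custom")
        if self.kind not in kinds:
            raise DomainError(f"kind must be one of {kinds}, got {self.kind!r}")
        if self.w is None:
            self.w = DEFAULT_W_SIMILARITY if self.kind == "similarity_qed" else DEFAULT_W_MQED
        _check_weight(self.w)
        if self.kind == "similarity_qed":
            if not self.reference:
                raise MissingReference("similarity_qed needs a reference molecule")
            self.reference = canonicalize(self.reference)
        if self.kind == "custom" and self.custom_fn is None:
            raise DomainError("custom objective needs custom_fn")
        self._ref_record = (
            MoleculeRecord(canonical_smiles=self.reference) if self.reference else None
        )


def similarity_qed(mol: MoleculeRecord, ref: MoleculeRecord, w: float = DEFAULT_W_SIMILARITY) -> float:
    """``w * morgan_tanimoto(mol, ref) + (1 - w) * qed(mol)``."""
    _check_weight(w)
    sim = tanimoto(mol.fingerprint(FP_MORGAN), ref.fingerprint(FP_MORGAN))
    qed, _ = qed_sa(mol.canonical_smiles)
    return w * sim + (1.0 - w) * qed


def score(mol: str, spec: ObjectiveSpec, generation_born: int = 0) -> MoleculeRecord:
    """Score a molecule under an objective, returning a full record.

    The record's ``breakdown`` carries the component property scores so
    that ``objective_value`` is recomputable from them.
    """
    record = MoleculeRecord(
        canonical_smiles=canonicalize(mol), generation_born=generation_born
    )
    if spec.kind == "custom":
        record.objective_value = float(spec.custom_fn(record))
        return record

    qed, sa = qed_sa(record.canonical_smiles)
    record.breakdown = {"qed": qed, "sa": sa}
    if spec.kind == "mqed":
        record.objective_value = mqed(qed, sa, spec.w)
    elif spec.kind == "normalized_mqed":
        record.objective_value = normalized_mqed(qed, sa, spec.w)
    else:  # similarity_qed
        sim = tanimoto(
            record.fingerprint(FP_MORGAN), spec._ref_record.fingerprint(FP_MORGAN)
        )
        record.breakdown["sim"] = sim
        record.objective_value = spec.w * sim + (1.0 - spec.w) * qed
    return record
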