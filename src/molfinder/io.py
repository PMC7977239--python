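"""File formats: .smi seed files, result CSVs, run manifests."""

from __future__ import annotations

import json
import os
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .analysis import ACYCLIC_SCAFFOLD
from .engine import Bank, RunConfig, RunResult
from .errors import EmptyInput
from .molecule import is_valid, murcko_scaffold

RESULT_COLUMNS = [
    "canonical_smiles",
    "objective_value",
    "qed",
    "sa",
    "sim",
    "scaffold",
    "generation_born",
]


def read_smiles_file(path: str | os.PathLike) -> tuple[list[str], list[str]]:
    """Read a .smi file: one molecule per line, SMILES first, optional name.

    Blank lines and ``#`` comments are ignored.  Returns
    ``(smiles, warnings)`` where warnings describe unparseable lines;
    raises :class:`EmptyInput` if no line yields a valid molecule.
    """
    path = Path(path)
    smiles: list[str] = []
    warnings: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split()[0]
            if is_valid(token):
                smiles.append(token)
            else:
                warnings.append(f"{path.name}:{lineno}: invalid SMILES {token!r}")
    if not smiles:
        raise EmptyInput(f"no valid molecules in {path}")
    return smiles, warnings


def write_smiles_file(smiles: list[str], path: str | os.PathLike, names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(smiles):
            name = names[i] if names else f"mol{i}"
            fh.write(f"{s} {name}\n")


def bank_to_frame(bank: Bank) -> pd.DataFrame:
    """One row per bank member, best objective first."""
    rows = []
    for r in sorted(
        bank.records, key=lambda r: (-r.objective_value, r.canonical_smiles)
    ):
        scaffold = murcko_scaffold(r.canonical_smiles) or ACYCLIC_SCAFFOLD
        rows.append(
            {
                "canonical_smiles": r.canonical_smiles,
                "objective_value": r.objective_value,
                "qed": r.breakdown.get("qed"),
                "sa": r.breakdown.get("sa"),
                "sim": r.breakdown.get("sim"),
                "scaffold": scaffold,
                "generation_born": r.generation_born,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(bank: Bank, path: str | os.PathLike) -> pd.DataFrame:
    """Write the final bank as a CSV plus a sibling .smi file."""
    if not bank.records:
        raise ValueError("refusing to write an empty bank")
    path = Path(path)
    frame = bank_to_frame(bank)
    frame.to_csv(path, index=False)
    write_smiles_file(
        frame["canonical_smiles"].tolist(),
        path.with_suffix(".smi"),
        names=[f"rank{i}" for i in range(len(frame))],
    )
    return frame


def write_manifest(result: RunResult, config: RunConfig, path: str | os.PathLike) -> None:
    """Machine-readable echo of the run: config, operator stats, version."""
    from . import __version__

    cfg = asdict(config)
    cfg["objective"] = {
        "kind": config.objective.kind,
        "w": config.objective.w,
        "reference": config.objective.reference,
    }
    cfg.pop("custom_fn", None)
    manifest = {
        "version": __version__,
        "config": cfg,
        "generations_run": result.final_bank.generation,
        "d_avg": result.final_bank.d_avg,
        "d_cut_final": result.final_bank.d_cut,
        "best_objective": result.all_time_best.objective_value,
        "best_smiles": result.all_time_best.canonical_smiles,
        "operator_stats": {
            k: {"attempts": v.attempts, "valid": v.valid, "discarded_pairs": v.discarded_pairs}
            for k, v in result.operator_stats.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def write_trajectory(result: RunResult, path: str | os.PathLike) -> None:
    pd.DataFrame(result.trajectory).to_csv(path, index=False)
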