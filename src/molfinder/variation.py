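"""SMILES-level genetic operators: ring-aware crossover and valence-aware mutations.

The operators act directly on the SMILES text (crossover, insertion,
deletion) or on the molecular graph (substitution).  Random string edits
mostly break SMILES syntax, so each operator embeds the repairs that make
the edit likely to survive parsing:

* crossover never truncates inside a ring (a cut point must leave every
  ring-closure digit of the retained substring paired) and repairs
  unbalanced branch parentheses before validation;
* insertion and deletion act on whole atom tokens, never mid-token;
* substitution replaces an atom by an element whose maximum valence
  accommodates the atom's existing bonds.

The toolkit's sanitizer is always the final arbiter of validity; every
operator retries with fresh random choices up to a fixed budget and
returns ``None`` when the budget is exhausted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import NoAdmissibleCut, ParseError, TooSmall
from .molecule import (
    MoleculeRecord,
    heavy_atom_count,
    is_valid,
    mol_from_smiles,
    safe_canonical,
)

from rdkit import Chem

#: Elements the mutation operators may introduce, with their maximum valence.
MUTATION_ALPHABET = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 6, "P": 5, "F": 1, "Cl": 1, "Br": 1, "I": 1}
#: Elements with a lowercase aromatic form.
AROMATIC_CAPABLE = frozenset("CNOSP")

DEFAULT_TRIES = 30

_TOKEN_RE = re.compile(
    r"\[[^\]]*\]"      # bracket atom, one token
    r"|Br|Cl"          # two-letter organic-subset elements
    r"|%\d{2}"         # two-digit ring-closure label
    r"|[A-Za-z]"       # one-letter element / aromatic symbol
    r"|\d"             # ring-closure digit
    r"|."              # bonds, branches, dots, anything else
)

def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into atomic-edit tokens.

    Bracket atoms, two-letter elements and ``%nn`` ring labels are single
    tokens; every other character stands alone.
    """
    return _TOKEN_RE.findall(smiles)


def is_atom_token(token: str) -> bool:
    if token.startswith("["):
        return True
    if token in ("Br", "Cl"):
        return True
    return len(token) == 1 and token in "BCNOPSFIbcnops"


def _is_aromatic_atom_token(token: str) -> bool:
    if len(token) == 1 and token in "bcnops":
        return True
    return token.startswith("[") and bool(re.match(r"\[\d*[bcnops]", token))


def _ring_spans(smiles: str) -> list[tuple[int, int]]:
    """Character spans (open_token_end, close_token_end) of ring-bond pairs.

    A cut at character position ``i`` severs pair ``(o, c)`` exactly when
    ``o <= i < c``: the left part then contains the opening digit but not
    the closing one (and the right part the converse).
    """
    spans: list[tuple[int, int]] = []
    open_at: dict[str, int] = {}
    pos = 0
    for tok in tokenize(smiles):
        end = pos + len(tok)
        if tok.isdigit() or tok.startswith("%"):
            label = tok.lstrip("%")
            if label in open_at:
                spans.append((open_at.pop(label), end))
            else:
                open_at[label] = end
        pos = end
    return spans


@dataclass(frozen=True)
class CutPoint:
    """A ring-safe truncation point in a SMILES string."""

    index: int
    side: str  # "keep-left" | "keep-right"


def admissible_cut_indices(smiles: str) -> list[int]:
    """All proper cut positions that sever no ring-bond pair.

    Candidate positions are token boundaries strictly inside the string,
    so a cut can never split a two-character element or a bracket atom.
    The admissible set is side-independent: a cut severs a ring pair for
    the left-kept part exactly when it does for the right-kept part.
    """
    boundaries = []
    pos = 0
    for tok in tokenize(smiles):
        pos += len(tok)
        if pos < len(smiles):
            boundaries.append(pos)
    spans = _ring_spans(smiles)
    return [i for i in boundaries if not any(o <= i < c for o, c in spans)]


def select_cut_point(smiles: str, side: str, rng: np.random.Generator) -> CutPoint:
    """Draw a cut index uniformly from the admissible set."""
    if side not in ("keep-left", "keep-right"):
        raise ValueError(f"side must be keep-left or keep-right, got {side!r}")
    admissible = admissible_cut_indices(smiles)
    if not admissible:
        raise NoAdmissibleCut(f"no ring-safe cut in {smiles!r}")
    return CutPoint(index=int(rng.choice(admissible)), side=side)


def balance_parentheses(s: str, rng: np.random.Generator) -> str:
    """Equalize '(' and ')' counts by random removal or insertion.

    Excess closers are deleted uniformly at random among the closers.
    Deficient closers are inserted one at a time at positions chosen
    uniformly among those strictly after the first atom token where the
    branch nesting depth is positive, so every prefix of the result keeps
    ``#'(' >= #')'`` whenever the input's imbalance was a pure deficit.
    Characters other than parentheses are never touched.
    """
    n_open = s.count("(")
    n_close = s.count(")")
    if n_open == n_close:
        return s
    if n_close > n_open:
        closer_positions = [i for i, ch in enumerate(s) if ch == ")"]
        drop = set(rng.choice(closer_positions, size=n_close - n_open, replace=False).tolist())
        return "".join(ch for i, ch in enumerate(s) if i not in drop)
    # deficit of closers: insert after the first atom token only
    first_atom_end = 1
    pos = 0
    for tok in tokenize(s):
        pos += len(tok)
        if is_atom_token(tok):
            first_atom_end = pos
            break
    for _ in range(n_open - n_close):
        depth = 0
        candidates = []
        for i, ch in enumerate(s + " "):  # sentinel: position len(s) is insertable
            if i > first_atom_end and depth >= 1:
                candidates.append(i)
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
        if not candidates:  # no atom before any '(' — degenerate string
            candidates = [len(s)]
        at = int(rng.choice(candidates))
        s = s[:at] + ")" + s[at:]
    return s


@dataclass
class OperatorStats:
    """Attempt/validity bookkeeping for one operator."""

    attempts: int = 0
    valid: int = 0
    discarded_pairs: int = 0

    @property
    def rate(self) -> float:
        return self.valid / self.attempts if self.attempts else float("nan")

    def merge(self, other: "OperatorStats") -> None:
        self.attempts += other.attempts
        self.valid += other.valid
        self.discarded_pairs += other.discarded_pairs


def crossover(
    left_parent: str,
    right_parent: str,
    rng: np.random.Generator,
    max_tries: int = DEFAULT_TRIES,
    stats: OperatorStats | None = None,
) -> str | None:
    """Recombine two SMILES strings into one child molecule.

    One parent keeps a ring-safe left prefix, the other a ring-safe right
    suffix; the concatenation is parenthesis-repaired and validated.  Cut
    points are resampled fresh on every attempt.  After ``max_tries``
    failures the parents swap roles for another ``max_tries``; if no valid
    child is found the pair is discarded and ``None`` returned.
    """
    if not is_valid(left_parent):
        raise ParseError(f"invalid left parent: {left_parent!r}")
    if not is_valid(right_parent):
        raise ParseError(f"invalid right parent: {right_parent!r}")
    if stats is not None:
        stats.attempts += 1
    for a, b in ((left_parent, right_parent), (right_parent, left_parent)):
        cuts_a = admissible_cut_indices(a)
        cuts_b = admissible_cut_indices(b)
        if not cuts_a or not cuts_b:
            continue
        for _ in range(max_tries):
            i = int(rng.choice(cuts_a))
            j = int(rng.choice(cuts_b))
            child = balance_parentheses(a[:i] + b[j:], rng)
            if is_valid(child):
                canonical = safe_canonical(child)
                if canonical is None:
                    continue
                if stats is not None:
                    stats.valid += 1
                return canonical
    if stats is not None:
        stats.discarded_pairs += 1
    return None


def _insertion_symbol(tokens: list[str], pos: int, element: str) -> str:
    """Choose the aromatic or aliphatic spelling for an inserted element."""
    if element in AROMATIC_CAPABLE:
        before = next(
            (t for t in reversed(tokens[:pos]) if is_atom_token(t)), None
        )
        after = next((t for t in tokens[pos:] if is_atom_token(t)), None)
        if (
            before is not None
            and after is not None
            and _is_aromatic_atom_token(before)
            and _is_aromatic_atom_token(after)
        ):
            return element.lower()
    return element


def insert_atom(
    smiles: str,
    rng: np.random.Generator,
    max_tries: int = DEFAULT_TRIES,
    alphabet: tuple[str, ...] = MUTATION_ALPHABET,
    stats: OperatorStats | None = None,
) -> str | None:
    """Insert one atom token at a random position in the SMILES string."""
    parent_count = heavy_atom_count(smiles)  # raises ParseError if invalid
    tokens = tokenize(smiles)
    if stats is not None:
        stats.attempts += 1
    for _ in range(max_tries):
        pos = int(rng.integers(0, len(tokens) + 1))
        element = alphabet[int(rng.integers(0, len(alphabet)))]
        symbol = _insertion_symbol(tokens, pos, element)
        child = "".join(tokens[:pos] + [symbol] + tokens[pos:])
        if is_valid(child) and heavy_atom_count(child) == parent_count + 1:
            canonical = safe_canonical(child)
            if canonical is None:
                continue
            if stats is not None:
                stats.valid += 1
            return canonical
    return None


def delete_atom(
    smiles: str,
    rng: np.random.Generator,
    max_tries: int = DEFAULT_TRIES,
    stats: OperatorStats | None = None,
) -> str | None:
    """Delete one atom token at a random position in the SMILES string."""
    parent_count = heavy_atom_count(smiles)
    if parent_count < 2:
        raise TooSmall(f"cannot delete from single-atom molecule {smiles!r}")
    tokens = tokenize(smiles)
    atom_positions = [i for i, t in enumerate(tokens) if is_atom_token(t)]
    if stats is not None:
        stats.attempts += 1
    for _ in range(max_tries):
        pos = atom_positions[int(rng.integers(0, len(atom_positions)))]
        child = "".join(tokens[:pos] + tokens[pos + 1 :])
        if is_valid(child) and heavy_atom_count(child) == parent_count - 1:
            canonical = safe_canonical(child)
            if canonical is None:
                continue
            if stats is not None:
                stats.valid += 1
            return canonical
    return None


def substitute_atom(
    smiles: str,
    rng: np.random.Generator,
    max_tries: int = DEFAULT_TRIES,
    alphabet: tuple[str, ...] = MUTATION_ALPHABET,
    stats: OperatorStats | None = None,
) -> str | None:
    """Replace one atom by a different element that fits its bonding.

    Works on the molecular graph rather than the raw string: a random
    uncharged atom is rewritten to a random alphabet element whose maximum
    valence covers the atom's explicit valence, and the result is
    re-sanitized.  Heavy-atom count and bond topology are preserved.
    """
    mol = mol_from_smiles(smiles)
    n_atoms = mol.GetNumAtoms()
    if stats is not None:
        stats.attempts += 1
    pt = Chem.GetPeriodicTable()
    for _ in range(max_tries):
        idx = int(rng.integers(0, n_atoms))
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetFormalCharge() != 0:
            continue
        explicit = atom.GetExplicitValence()
        candidates = [
            e
            for e in alphabet
            if e != atom.GetSymbol() and MAX_VALENCE[e] >= explicit
        ]
        if atom.GetIsAromatic():
            candidates = [e for e in candidates if e in AROMATIC_CAPABLE]
        if not candidates:
            continue
        element = candidates[int(rng.integers(0, len(candidates)))]
        edited = Chem.RWMol(mol)
        new_atom = edited.GetAtomWithIdx(idx)
        new_atom.SetAtomicNum(pt.GetAtomicNumber(element))
        new_atom.SetNumExplicitHs(0)
        new_atom.SetNoImplicit(False)
        try:
            Chem.SanitizeMol(edited)
        except Exception:
            continue
        canonical = safe_canonical(Chem.MolToSmiles(edited))
        if canonical is not None:
            if stats is not None:
                stats.valid += 1
            return canonical
    return None


def generate_children(
    seed: MoleculeRecord,
    bank_pool: list[MoleculeRecord],
    rng: np.random.Generator,
    n_crossover: int = 40,
    n_per_mutation: int = 20,
    crossover_tries: int = DEFAULT_TRIES,
    mutation_tries: int = DEFAULT_TRIES,
    stats: dict[str, OperatorStats] | None = None,
) -> list[str]:
    """Spawn one seed molecule's batch of children.

    ``n_crossover`` crossover children, each with an independently drawn
    random partner from ``bank_pool``, plus ``n_per_mutation`` children
    from each of insertion, deletion and substitution.  Failed operator
    calls shrink the batch; survivors are deduplicated by canonical SMILES.
    """
    if not bank_pool:
        raise ValueError("bank_pool must be nonempty")
    if stats is None:
        stats = {}
    for key in ("crossover", "insert", "delete", "substitute"):
        stats.setdefault(key, OperatorStats())

    children: list[str] = []
    parent = seed.canonical_smiles
    for _ in range(n_crossover):
        partner = bank_pool[int(rng.integers(0, len(bank_pool)))]
        child = crossover(
            parent, partner.canonical_smiles, rng,
            max_tries=crossover_tries, stats=stats["crossover"],
        )
        if child is not None:
            children.append(child)
    for _ in range(n_per_mutation):
        child = insert_atom(parent, rng, max_tries=mutation_tries, stats=stats["insert"])
        if child is not None:
            children.append(child)
    for _ in range(n_per_mutation):
        try:
            child = delete_atom(parent, rng, max_tries=mutation_tries, stats=stats["delete"])
        except TooSmall:
            break
        if child is not None:
            children.append(child)
    for _ in range(n_per_mutation):
        child = substitute_atom(parent, rng, max_tries=mutation_tries, stats=stats["substitute"])
        if child is not None:
            children.append(child)

    seen: set[str] = set()
    unique: list[str] = []
    for c in children:
        if c not in seen:
            seen.add(c)
            unique.append(c)
    return unique
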