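"""Genetic operators: cut points, parenthesis repair, crossover, mutations."""

import re

import numpy as np
import pytest

import molfinder.variation as variation
from molfinder.errors import NoAdmissibleCut, ParseError, TooSmall
from molfinder.molecule import MoleculeRecord, canonicalize, heavy_atom_count, is_valid
from molfinder.variation import (
    admissible_cut_indices,
    balance_parentheses,
    crossover,
    delete_atom,
    generate_children,
    insert_atom,
    select_cut_point,
    substitute_atom,
    tokenize,
)

# --- independent oracle helpers -------------------------------------------

_ORACLE_TOKEN = re.compile(r"\[[^\]]*\]|Br|Cl|%\d{2}|.")


def _oracle_admissible(smiles):
    """Brute force: token boundaries whose prefix has even counts of every
    ring label (so no ring-closure digit is left half-open on either side)."""
    tokens = _ORACLE_TOKEN.findall(smiles)
    out, pos = [], 0
    counts_total = {}
    boundaries = []
    for t in tokens:
        pos += len(t)
        if pos < len(smiles):
            boundaries.append(pos)
    for i in boundaries:
        prefix = _ORACLE_TOKEN.findall(smiles[:i])
        counts = {}
        for t in prefix:
            if t.isdigit() or t.startswith("%"):
                lab = t.lstrip("%")
                counts[lab] = counts.get(lab, 0) + 1
        if all(v % 2 == 0 for v in counts.values()):
            out.append(i)
    return out


class TestTokenize:
    def test_roundtrip_on_fixture_set(self, drugs):
        for s in drugs:
            assert "".join(tokenize(s)) == s

    def test_multichar_tokens_intact(self):
        toks = tokenize("CC(Cl)c1ccc(Br)cc1[nH+]C%12CC%12")
        assert "Cl" in toks and "Br" in toks and "[nH+]" in toks and "%12" in toks


class TestCutPoints:
    def test_acyclic_all_proper_positions(self, rng):
        assert admissible_cut_indices("CCO") == [1, 2]
        cp = select_cut_point("CCO", "keep-left", rng)
        assert cp.index in (1, 2)

    def test_ring_span_never_cut(self):
        admissible = admissible_cut_indices("C1CCCCC1O")
        assert admissible == [1, 8]
        assert not any(2 <= i <= 7 for i in admissible)

    def test_matches_brute_force_oracle(self, drugs):
        for s in drugs[:50]:
            assert admissible_cut_indices(s) == _oracle_admissible(s)

    def test_single_atom_has_no_cut(self, rng):
        with pytest.raises(NoAdmissibleCut):
            select_cut_point("C", "keep-left", rng)

    def test_uniform_draw_covers_admissible_set(self, rng):
        seen = {select_cut_point("CCO", "keep-right", rng).index for _ in range(100)}
        assert seen == {1, 2}


class TestBalanceParentheses:
    def test_balanced_unchanged(self, rng):
        assert balance_parentheses("CC(C)C", rng) == "CC(C)C"

    def test_single_deficit_inserts_one_closer(self, rng):
        out = balance_parentheses("CC(C", rng)
        assert out.count("(") == out.count(")") == 1
        assert out.replace(")", "") == "CC(C"
        assert out.index(")") > out.index("(")

    def test_single_excess_removed(self, rng):
        assert balance_parentheses("CC)C", rng) == "CCC"

    def test_counts_match_and_multiset_preserved(self, drugs, rng):
        for s in drugs[:30]:
            # random paren corruption
            broken = s + "(" * int(rng.integers(0, 3)) + ")" * int(rng.integers(0, 3))
            fixed = balance_parentheses(broken, rng)
            assert fixed.count("(") == fixed.count(")")
            assert sorted(fixed.replace("(", "").replace(")", "")) == sorted(
                broken.replace("(", "").replace(")", "")
            )


class TestBalancePropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.text(alphabet="CNOc1()=", min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_counts_equal_and_other_chars_untouched(self, s):
        fixed = balance_parentheses(s, np.random.default_rng(0))
        assert fixed.count("(") == fixed.count(")")
        assert [c for c in fixed if c not in "()"] == [c for c in s if c not in "()"]


class TestCrossover:
    def test_children_valid_and_canonical(self, drugs, rng):
        for _ in range(300):
            a = drugs[int(rng.integers(0, len(drugs)))]
            b = drugs[int(rng.integers(0, len(drugs)))]
            child = crossover(a, b, rng)
            if child is not None:
                assert is_valid(child)
                assert canonicalize(child) == child

    def test_invalid_parent_rejected(self, rng):
        with pytest.raises(ParseError):
            crossover("C1CC", "CCO", rng)

    def test_retry_limit_returns_none(self, rng, monkeypatch):
        calls = {"n": 0}

        def stub_valid(s):
            # first two calls are the parent precondition checks; every
            # candidate child is then declared invalid
            calls["n"] += 1
            return calls["n"] <= 2

        monkeypatch.setattr(variation, "is_valid", stub_valid)
        assert crossover("CCO", "CCN", rng) is None
        assert calls["n"] == 62  # 2 parent checks + 30 tries + swap + 30 more

    def test_deterministic_under_seed(self, drugs):
        out1 = [
            crossover(drugs[i], drugs[i + 1], np.random.default_rng(9))
            for i in range(0, 20, 2)
        ]
        out2 = [
            crossover(drugs[i], drugs[i + 1], np.random.default_rng(9))
            for i in range(0, 20, 2)
        ]
        assert out1 == out2


class TestInsertAtom:
    def test_forced_outcome_single_element(self, rng):
        assert insert_atom("CC", rng, alphabet=("C",)) == "CCC"

    def test_adds_exactly_one_heavy_atom(self, drugs, rng):
        for s in drugs[:40]:
            child = insert_atom(s, rng)
            if child is not None:
                assert heavy_atom_count(child) == heavy_atom_count(s) + 1

    def test_invalid_parent(self, rng):
        with pytest.raises(ParseError):
            insert_atom("C1CC", rng)


class TestDeleteAtom:
    def test_propane_to_ethane(self, rng):
        assert delete_atom("CCC", rng) == "CC"

    def test_single_atom_too_small(self, rng):
        with pytest.raises(TooSmall):
            delete_atom("C", rng)

    def test_removes_exactly_one_heavy_atom(self, drugs, rng):
        for s in drugs[:40]:
            child = delete_atom(s, rng)
            if child is not None:
                assert heavy_atom_count(child) == heavy_atom_count(s) - 1


class TestSubstituteAtom:
    def test_single_atom_any_replacement(self, rng):
        assert substitute_atom("C", rng, alphabet=("N", "O")) in ("N", "O")

    def test_preserves_heavy_atom_count(self, drugs, rng):
        for s in drugs[:40]:
            child = substitute_atom(s, rng)
            if child is not None:
                assert heavy_atom_count(child) == heavy_atom_count(s)

    def test_reachable_set_matches_string_enumeration_oracle(self, rng):
        # oracle: exhaustively replace each atom character of "CCO" with
        # each alphabet element at the string level and keep what parses
        parent = "CCO"
        degrees = (1, 2, 1)  # explicit connections of C, C, O in ethanol
        oracle = set()
        for pos in range(3):
            for elem in variation.MUTATION_ALPHABET:
                if elem == parent[pos]:
                    continue
                if variation.MAX_VALENCE[elem] < degrees[pos]:
                    continue
                cand = parent[:pos] + elem + parent[pos + 1 :]
                if is_valid(cand):
                    oracle.add(canonicalize(cand))
        reached = set()
        for _ in range(600):
            child = substitute_atom(parent, rng)
            if child is not None:
                reached.add(child)
        assert reached == oracle

    def test_quaternary_carbon_never_becomes_halogen(self, rng):
        from rdkit import Chem

        for _ in range(100):
            child = substitute_atom("CC(C)(C)C", rng)
            if child is None:
                continue
            mol = Chem.MolFromSmiles(child)
            for atom in mol.GetAtoms():
                if atom.GetSymbol() in ("F", "Cl", "Br", "I"):
                    assert atom.GetDegree() <= 1


class TestGenerateChildren:
    def _records(self, smiles):
        return [MoleculeRecord(canonical_smiles=s) for s in smiles]

    def test_child_count_bounded(self, drugs, rng):
        seed = MoleculeRecord(canonical_smiles=drugs[0])
        children = generate_children(seed, self._records(drugs[:20]), rng)
        assert len(children) <= 100
        assert len(set(children)) == len(children)
        assert all(is_valid(c) for c in children)

    def test_stubbed_operators_give_full_batch(self, rng, monkeypatch):
        counter = {"n": 0}

        def fake_op(*args, **kwargs):
            counter["n"] += 1
            return f"C{'C' * counter['n']}"  # distinct alkanes

        monkeypatch.setattr(variation, "crossover", fake_op)
        monkeypatch.setattr(variation, "insert_atom", fake_op)
        monkeypatch.setattr(variation, "delete_atom", fake_op)
        monkeypatch.setattr(variation, "substitute_atom", fake_op)
        seed = MoleculeRecord(canonical_smiles="CCO")
        children = generate_children(seed, self._records(["CCN"]), rng)
        assert len(children) == 100

    def test_reproducible_under_seed(self, drugs):
        seed = MoleculeRecord(canonical_smiles=drugs[3])
        pool = self._records(drugs[:30])
        c1 = generate_children(seed, pool, np.random.default_rng(77))
        c2 = generate_children(seed, pool, np.random.default_rng(77))
        assert c1 == c2
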