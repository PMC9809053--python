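"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles — per-atom
exhaustive neighbourhood inspection, exhaustive subchain enumeration —
and share no code path with the package internals they check.
"""

from itertools import combinations

from rdkit import Chem

_ONS_SYMBOLS = {"N", "O", "S"}


def _is_single(bond) -> bool:
    return bond.GetBondType() == Chem.BondType.SINGLE


def _three_rings_brute_force(mol):
    """All 3-membered rings found by exhaustive triple enumeration."""
    n = mol.GetNumAtoms()
    for i, j, k in combinations(range(n), 3):
        if (
            mol.GetBondBetweenAtoms(i, j)
            and mol.GetBondBetweenAtoms(j, k)
            and mol.GetBondBetweenAtoms(i, k)
        ):
            yield (i, j, k)


def oracle_marked_atoms(mol) -> set[int]:
    """Brute-force functional-group atom marking, atom by atom."""
    marked = set()
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        symbol = atom.GetSymbol()
        # rule 1: heteroatom
        if symbol not in ("C", "H"):
            marked.add(idx)
            continue
        if symbol != "C":
            continue
        # rules 2 and 3: multiple bonds
        for bond in atom.GetBonds():
            if bond.GetIsAromatic():
                continue
            if bond.GetBondType() not in (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE):
                continue
            other = bond.GetOtherAtom(atom)
            if other.GetSymbol() == "C" or other.GetSymbol() not in ("C", "H"):
                marked.add(idx)
        if idx in marked:
            continue
        # rule 4: acetal-like carbon
        if not atom.GetIsAromatic() and all(_is_single(b) for b in atom.GetBonds()):
            qualifying = 0
            for bond in atom.GetBonds():
                other = bond.GetOtherAtom(atom)
                if other.GetSymbol() in _ONS_SYMBOLS and all(
                    _is_single(b) for b in other.GetBonds()
                ):
                    qualifying += 1
            if qualifying >= 2:
                marked.add(idx)
    # rule 5: heteroatom-containing three-rings, by exhaustive triples
    for ring in _three_rings_brute_force(mol):
        if any(mol.GetAtomWithIdx(i).GetSymbol() not in ("C", "H") for i in ring):
            marked.update(ring)
    return marked


# --- scaffold subchain oracle ----------------------------------------------

#: The three-ring linear chain fixture: cyclohexane - benzene - pyridine,
#: CH2 linkers.  Hand-written SMILES for every contiguous subchain.
THREE_RING_CHAIN = "C1CCCCC1Cc1ccc(Cc2ccncc2)cc1"
_SUBCHAIN_SMILES = {
    (0,): "C1CCCCC1",
    (1,): "c1ccccc1",
    (2,): "c1ccncc1",
    (0, 1): "C1CCCCC1Cc1ccccc1",
    (1, 2): "c1ccc(Cc2ccncc2)cc1",
    (0, 1, 2): THREE_RING_CHAIN,
}


def oracle_subchain_parents() -> set[str]:
    """Exhaustively enumerate the contiguous proper subchains of the
    three-ring linear chain; returns their hand-written SMILES."""
    n = 3
    subchains = set()
    for start in range(n):
        for end in range(start + 1, n + 1):
            chain = tuple(range(start, end))
            if len(chain) < n:  # proper subchains only
                subchains.add(chain)
    return {_SUBCHAIN_SMILES[chain] for chain in subchains}
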