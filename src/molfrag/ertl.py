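"""Functional-group identification by atom marking.

Implements the Ertl approach to rule-based functional-group perception:
atoms are first *marked* by five structural rules, then every connected
component of marked atoms becomes one functional-group fragment, carrying
its first-sphere unmarked carbon neighbours as environment atoms.  The
unmarked complement yields carbon-skeleton remnant fragments.

Marking rules
-------------
1. every heteroatom (not C, not H);
2. every carbon in a non-aromatic C=C or C#C bond;
3. every carbon double- or triple-bonded to a heteroatom;
4. every acetal-like sp3 carbon: >= 2 single bonds to O/N/S atoms that
   themselves bear only single bonds;
5. all atoms of three-membered rings containing a heteroatom.

An atom's primary reason is the first rule (in this order) that marks it.

Environment depiction
---------------------
Environment carbons keep their aromatic/aliphatic typing — an aromatic
attachment is written in lower case even outside a ring, as in the
hydroxy-on-aromatic-carbon group ``[H]Oc``.  In *generalized* mode the
environment carbons carry no hydrogen specification of their own; in
*full* mode they keep their real hydrogen counts (written explicitly
where they differ from the SMILES default).  Cleaved bonds carry no
attachment labels.

The algorithm requires neutral, organic-subset input; metal- or
metalloid-containing structures are filtered and charges are neutralised
in preprocessing (non-neutralisable molecules are demoted to FILTERED).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem

from .chemio import canonicalise, extract_fragments
from .fragmenter import (
    MoleculeFragmenter,
    SettingDescriptor,
    ValueType,
    neutralise_charges,
    register,
)

#: Elements the algorithm accepts: the organic subset plus selenium.
ORGANIC_SUBSET = frozenset({1, 6, 7, 8, 9, 15, 16, 17, 34, 35, 53})

_MULTI = (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
_ONS = (7, 8, 16)


class MarkReason(enum.Enum):
    HETEROATOM = "heteroatom"
    C_C_MULTIBOND = "carbon in non-aromatic multiple C-C bond"
    C_MULTIBOND_HETERO = "carbon multiple-bonded to heteroatom"
    ACETAL_C = "acetal-like carbon"
    THREE_RING_HETERO = "atom of heteroatom-containing three-ring"


@dataclass
class AtomMarking:
    """Marked atom indices with one primary reason per atom."""

    marked: set[int] = field(default_factory=set)
    reason: dict[int, MarkReason] = field(default_factory=dict)


def mark_atoms(mol: Chem.Mol) -> AtomMarking:
    """Apply the five marking rules; deterministic."""
    reason: dict[int, MarkReason] = {}

    # rule 1: heteroatoms
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in (1, 6):
            reason.setdefault(atom.GetIdx(), MarkReason.HETEROATOM)

    # rule 2: carbons in non-aromatic multiple C-C bonds
    for bond in mol.GetBonds():
        if bond.GetBondType() in _MULTI and not bond.GetIsAromatic():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            if a.GetAtomicNum() == 6 and b.GetAtomicNum() == 6:
                reason.setdefault(a.GetIdx(), MarkReason.C_C_MULTIBOND)
                reason.setdefault(b.GetIdx(), MarkReason.C_C_MULTIBOND)

    # rule 3: carbons multiple-bonded to heteroatoms
    for bond in mol.GetBonds():
        if bond.GetBondType() in _MULTI and not bond.GetIsAromatic():
            a, b = bond.GetBeginAtom(), bond.GetEndAtom()
            for carbon, other in ((a, b), (b, a)):
                if carbon.GetAtomicNum() == 6 and other.GetAtomicNum() not in (1, 6):
                    reason.setdefault(carbon.GetIdx(), MarkReason.C_MULTIBOND_HETERO)

    # rule 4: acetal-like sp3 carbons
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
            continue
        single_ons = 0
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom)
            if other.GetAtomicNum() in _ONS and all(
                nb.GetBondType() == Chem.BondType.SINGLE for nb in other.GetBonds()
            ):
                single_ons += 1
        if single_ons >= 2:
            reason.setdefault(atom.GetIdx(), MarkReason.ACETAL_C)

    # rule 5: heteroatom-containing three-membered rings
    for ring in mol.GetRingInfo().AtomRings():
        if len(ring) == 3 and any(
            mol.GetAtomWithIdx(i).GetAtomicNum() not in (1, 6) for i in ring
        ):
            for i in ring:
                reason.setdefault(i, MarkReason.THREE_RING_HETERO)

    return AtomMarking(marked=set(reason), reason=reason)


def _connected_components(mol: Chem.Mol, atoms: set[int]) -> list[set[int]]:
    """Connected components of ``atoms`` under the molecule's bonds,
    in deterministic (lowest-index-first) order."""
    remaining = set(atoms)
    components = []
    while remaining:
        seed = min(remaining)
        component = {seed}
        frontier = [seed]
        while frontier:
            idx = frontier.pop()
            for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = nb.GetIdx()
                if j in remaining and j not in component:
                    component.add(j)
                    frontier.append(j)
        remaining -= component
        components.append(component)
    return components


def extract_functional_groups(
    mol: Chem.Mol, marking: AtomMarking, environment_mode: str = "generalized"
) -> list[str]:
    """One fragment per connected component of marked atoms, with
    first-sphere unmarked carbon environment; canonical SMILES."""
    if not marking.marked:
        return []
    # In full mode every atom is written with its real hydrogen count;
    # canonicalisation folds standard counts back to bare atoms, so only
    # environments deviating from the SMILES default stay bracketed.
    all_hs = environment_mode == "full"
    fragments = []
    for component in _connected_components(mol, marking.marked):
        atoms = set(component)
        bonds = []
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in component and j in component:
                bonds.append(bond.GetIdx())
                continue
            # core–environment bond: pull in unmarked carbon neighbours
            for core, envir in ((i, j), (j, i)):
                if core in component and envir not in marking.marked:
                    env_atom = mol.GetAtomWithIdx(envir)
                    if env_atom.GetAtomicNum() == 6:
                        atoms.add(envir)
                        bonds.append(bond.GetIdx())
        smiles = Chem.MolFragmentToSmiles(
            mol, atomsToUse=sorted(atoms), bondsToUse=bonds, canonical=True,
            allHsExplicit=all_hs,
        )
        fragments.append(canonicalise(smiles))
    return fragments


def extract_remnants(mol: Chem.Mol, marking: AtomMarking) -> list[str]:
    """One hydrogen-saturated fragment per connected component of
    unmarked heavy atoms."""
    unmarked = set(range(mol.GetNumAtoms())) - marking.marked
    return [canonicalise(s) for s in extract_fragments(mol, unmarked)]


@register
class ErtlFunctionalGroupFragmenter(MoleculeFragmenter):
    """Functional groups plus carbon-skeleton remnants as fragments."""

    identifier = "ertl-fg"
    setting_descriptors = (
        SettingDescriptor(
            "environment_mode",
            ValueType.ENUM,
            "generalized",
            "Depiction of first-sphere environment carbons: 'generalized' "
            "(no hydrogen specification of their own) or 'full' (real "
            "hydrogen counts).",
            allowed=("generalized", "full"),
        ),
        SettingDescriptor(
            "return_remnants",
            ValueType.BOOLEAN,
            True,
            "Also return the hydrogen-saturated carbon-skeleton remnants "
            "left after functional-group extraction.",
        ),
    )

    def should_filter(self, mol: Chem.Mol) -> tuple[bool, str]:
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() not in ORGANIC_SUBSET:
                return True, f"metal or metalloid atom: {atom.GetSymbol()}"
        return False, ""

    def preprocess(self, mol: Chem.Mol) -> Optional[Chem.Mol]:
        return neutralise_charges(mol)

    def fragment(self, mol: Chem.Mol) -> list[str]:
        if mol.GetNumAtoms() == 0:
            return []
        marking = mark_atoms(mol)
        fragments = extract_functional_groups(
            mol, marking, self.settings["environment_mode"]
        )
        if self.settings["return_remnants"]:
            fragments += extract_remnants(mol, marking)
        return fragments
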