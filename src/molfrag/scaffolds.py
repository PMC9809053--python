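"""Molecular scaffolds: extraction, dissection and parent enumeration.

A scaffold (Murcko framework) is the union of a molecule's ring systems
and the linker atoms connecting them, obtained by iteratively pruning
terminal acyclic atoms.  Exocyclic double- and triple-bonded atoms
attached to retained atoms (e.g. a ring carbonyl oxygen) belong to the
scaffold.  Ring systems are the components of ring atoms under ring
bonds, so fused and spiro rings form one system.

Parent scaffolds are enumerated breadth-first by removing one terminal
ring at a time — a ring whose exclusive atoms can be deleted, followed by
re-pruning of the exposed linkers, leaving a connected scaffold — down to
single rings.  This is the network-style enumerative routine; no
chemistry-rule prioritisation is applied.  :func:`tree_path` offers a
single documented linear path (smallest terminal ring first, ties by
canonical order) for tree-like use.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem

from .chemio import canonicalise, extract_fragments, parse_smiles
from .fragmenter import MoleculeFragmenter, SettingDescriptor, ValueType, register

logger = logging.getLogger(__name__)

_MULTI = (Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)


class FragmentationType(enum.Enum):
    SCAFFOLD_ONLY = "SCAFFOLD_ONLY"
    SIDE_CHAINS_ONLY = "SIDE_CHAINS_ONLY"
    RINGS_AND_LINKERS = "RINGS_AND_LINKERS"
    ENUMERATIVE_PARENTS = "ENUMERATIVE_PARENTS"


@dataclass
class ScaffoldParts:
    """Atom-level partition of a molecule into scaffold and side chains.

    ``scaffold_atoms`` is the union of the ring systems and the linker
    atoms; side chains are the connected components of the complement.
    Every heavy atom is in exactly one category.
    """

    scaffold_atoms: set[int] = field(default_factory=set)
    ring_systems: list[set[int]] = field(default_factory=list)
    linker_atoms: set[int] = field(default_factory=set)
    side_chains: list[set[int]] = field(default_factory=list)


def _components(atoms: set[int], neighbours) -> list[set[int]]:
    remaining = set(atoms)
    out = []
    while remaining:
        seed = min(remaining)
        comp = {seed}
        frontier = [seed]
        while frontier:
            i = frontier.pop()
            for j in neighbours(i):
                if j in remaining and j not in comp:
                    comp.add(j)
                    frontier.append(j)
        remaining -= comp
        out.append(comp)
    return out


def scaffold_parts(mol: Chem.Mol) -> Optional[ScaffoldParts]:
    """Classify every heavy atom; ``None`` for acyclic molecules."""
    ring_info = mol.GetRingInfo()
    ring_atoms = {i for ring in ring_info.AtomRings() for i in ring}
    if not ring_atoms:
        return None

    # iterative pruning of terminal acyclic atoms -> rings + linkers
    remaining = set(range(mol.GetNumAtoms()))
    while True:
        prunable = set()
        for i in remaining:
            if i in ring_atoms:
                continue
            degree = sum(
                nb.GetIdx() in remaining for nb in mol.GetAtomWithIdx(i).GetNeighbors()
            )
            if degree <= 1:
                prunable.add(i)
        if not prunable:
            break
        remaining -= prunable
    linker_atoms = remaining - ring_atoms

    # ring systems: components of ring atoms under ring bonds
    ring_adjacency: dict[int, set[int]] = {i: set() for i in ring_atoms}
    for bond in mol.GetBonds():
        if bond.IsInRing():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            ring_adjacency[i].add(j)
            ring_adjacency[j].add(i)
    ring_systems = _components(ring_atoms, lambda i: ring_adjacency[i])

    # exocyclic multiple-bonded atoms join the category of their anchor
    scaffold = ring_atoms | linker_atoms
    for bond in mol.GetBonds():
        if bond.GetBondType() not in _MULTI:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        for inside, outside in ((i, j), (j, i)):
            if inside in scaffold and outside not in scaffold:
                scaffold.add(outside)
                if inside in ring_atoms:
                    next(rs for rs in ring_systems if inside in rs).add(outside)
                else:
                    linker_atoms.add(outside)

    side_atoms = set(range(mol.GetNumAtoms())) - scaffold
    side_chains = _components(
        side_atoms,
        lambda i: (nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors()),
    )
    return ScaffoldParts(
        scaffold_atoms=scaffold,
        ring_systems=ring_systems,
        linker_atoms=linker_atoms,
        side_chains=side_chains,
    )


def murcko_scaffold(mol: Chem.Mol) -> Optional[str]:
    """Canonical SMILES of the molecular scaffold; ``None`` when acyclic."""
    parts = scaffold_parts(mol)
    if parts is None:
        return None
    frags = extract_fragments(mol, parts.scaffold_atoms)
    return canonicalise(".".join(frags))


def dissect(mol: Chem.Mol, fragmentation_type: FragmentationType | str) -> list[str]:
    """Dissect per the configured mode; acyclic input yields an empty
    list with a logged warning."""
    if isinstance(fragmentation_type, str):
        fragmentation_type = FragmentationType(fragmentation_type)
    parts = scaffold_parts(mol)
    if parts is None:
        logger.warning("acyclic molecule has no scaffold: %s", Chem.MolToSmiles(mol))
        return []
    if fragmentation_type is FragmentationType.SCAFFOLD_ONLY:
        return [canonicalise(".".join(extract_fragments(mol, parts.scaffold_atoms)))]
    if fragmentation_type is FragmentationType.SIDE_CHAINS_ONLY:
        out = []
        for chain in parts.side_chains:
            out += [canonicalise(s) for s in extract_fragments(mol, chain)]
        return out
    if fragmentation_type is FragmentationType.RINGS_AND_LINKERS:
        out = []
        for system in parts.ring_systems:
            out += [canonicalise(s) for s in extract_fragments(mol, system)]
        for linker in _components(
            parts.linker_atoms,
            lambda i: (nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors()),
        ):
            out += [canonicalise(s) for s in extract_fragments(mol, linker)]
        return out
    scaffold = murcko_scaffold(mol)
    return sorted(enumerate_parents(parse_smiles(scaffold)))


def _direct_parents(mol: Chem.Mol) -> set[str]:
    """Parents reachable by removing one terminal ring, as canonical SMILES."""
    ring_info = mol.GetRingInfo()
    rings = ring_info.AtomRings()
    if len(rings) <= 1:
        return set()
    parents = set()
    for ring in rings:
        exclusive = {i for i in ring if ring_info.NumAtomRings(i) == 1}
        if not exclusive:
            continue
        # exocyclic multiple-bonded partners of deleted atoms go too
        extras = set()
        for i in exclusive:
            for bond in mol.GetAtomWithIdx(i).GetBonds():
                if bond.GetBondType() in _MULTI:
                    other = bond.GetOtherAtomIdx(i)
                    if other not in exclusive and not mol.GetAtomWithIdx(other).IsInRing():
                        extras.add(other)
        keep = set(range(mol.GetNumAtoms())) - exclusive - extras
        remainder = extract_fragments(mol, keep)
        if len(remainder) != 1:
            continue  # removal disconnects the scaffold: not a terminal ring
        parent = murcko_scaffold(parse_smiles(remainder[0]))
        if parent is not None and "." not in parent:
            parents.add(parent)
    return parents


def enumerate_parents(mol: Chem.Mol) -> set[str]:
    """All distinct parent scaffolds down to single rings (breadth-first
    terminal-ring removal); the input itself is excluded."""
    parents: set[str] = set()
    queue = [Chem.MolToSmiles(mol)]
    while queue:
        current = queue.pop(0)
        for parent in _direct_parents(parse_smiles(current)):
            if parent not in parents:
                parents.add(parent)
                queue.append(parent)
    return parents


def tree_path(mol: Chem.Mol) -> list[str]:
    """A single linear parent path: repeatedly remove the smallest
    terminal ring, ties broken by canonical order of the resulting parent."""
    path = []
    current = Chem.MolToSmiles(mol)
    while True:
        cmol = parse_smiles(current)
        ring_info = cmol.GetRingInfo()
        candidates = []
        for ring in ring_info.AtomRings():
            exclusive = {i for i in ring if ring_info.NumAtomRings(i) == 1}
            if not exclusive:
                continue
            keep = set(range(cmol.GetNumAtoms())) - exclusive
            remainder = extract_fragments(cmol, keep)
            if len(remainder) != 1:
                continue
            parent = murcko_scaffold(parse_smiles(remainder[0]))
            if parent is not None and "." not in parent:
                candidates.append((len(ring), parent))
        if not candidates:
            break
        _, current = min(candidates)
        path.append(current)
    return path


@register
class ScaffoldFragmenter(MoleculeFragmenter):
    """Scaffold extraction and dissection as a fragmenter plugin."""

    identifier = "scaffold"
    setting_descriptors = (
        SettingDescriptor(
            "fragmentation_type",
            ValueType.ENUM,
            "SCAFFOLD_ONLY",
            "What to return: the scaffold itself, the pruned side chains, "
            "the ring systems and linkers, or all enumerated parent "
            "scaffolds.",
            allowed=tuple(t.value for t in FragmentationType),
        ),
    )

    def fragment(self, mol: Chem.Mol) -> list[str]:
        if mol.GetNumAtoms() == 0:
            return []
        return dissect(mol, self.settings["fragmentation_type"])
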