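"""Detection and removal of glycosidic moieties.

Circular sugars are non-fused furanose/pyranose-sized rings (5 or 6
atoms) with exactly one ring oxygen, all ring carbons sp3, and an
exocyclic single-bonded oxygen density of at least
``exocyclic_oxygen_ratio_min``.  Linear sugars are acyclic chains of 3–7
carbons each bearing exactly one oxygen substituent (hydroxy or
carbonyl); stereochemistry is ignored throughout.

Removal iteratively deletes detected moieties — terminal ones only, by
default — saturating cut bonds with hydrogen.  The glycosidic bridging
oxygen stays with the aglycone, so an ether to a removed ring becomes a
hydroxy group.  Disconnected leftovers below ``min_aglycone_heavy_atoms``
heavy atoms (freed hydroxymethyl arms and the like) are discarded.  A
sugar moiety is *terminal* when its removal leaves at most one
substantial (above-threshold) component behind.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from rdkit import Chem

from .chemio import canonicalise, extract_fragments, parse_smiles
from .fragmenter import MoleculeFragmenter, SettingDescriptor, ValueType, register


class SugarKind(enum.Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


@dataclass
class SugarHit:
    """One detected glycosidic moiety."""

    kind: SugarKind
    atom_indices: frozenset[int]  # ring/chain atoms plus attached oxygens
    terminal: bool


_DEFAULTS = dict(
    detect_circular=True,
    detect_linear=False,
    remove_only_terminal=True,
    exocyclic_oxygen_ratio_min=0.5,
    min_aglycone_heavy_atoms=5,
    return_sugars=False,
)


def _settings(overrides: Optional[dict]) -> dict:
    merged = dict(_DEFAULTS)
    if overrides:
        merged.update(overrides)
    return merged


def _removal_set(mol: Chem.Mol, hit: SugarHit) -> set[int]:
    """Atoms actually deleted: the moiety minus oxygens that bridge to the
    remainder (those stay with the aglycone)."""
    removal = set()
    for idx in hit.atom_indices:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomicNum() == 8 and any(
            nb.GetIdx() not in hit.atom_indices and nb.GetAtomicNum() > 1
            for nb in atom.GetNeighbors()
        ):
            continue
        removal.add(idx)
    return removal


def _is_terminal(mol: Chem.Mol, removal: set[int], min_heavy: int) -> bool:
    keep = set(range(mol.GetNumAtoms())) - removal
    if not keep:
        return True
    substantial = 0
    for smiles in extract_fragments(mol, keep):
        if parse_smiles(smiles).GetNumHeavyAtoms() >= min_heavy:
            substantial += 1
    return substantial <= 1


def detect_circular_sugars(mol: Chem.Mol, settings: Optional[dict] = None) -> list[SugarHit]:
    """Find circular sugar moieties (ring plus its exocyclic oxygens)."""
    cfg = _settings(settings)
    ring_info = mol.GetRingInfo()
    rings = ring_info.AtomRings()
    hits = []
    for ring in rings:
        if len(ring) not in (5, 6):
            continue
        # non-fused: no atom shared with another ring
        if any(ring_info.NumAtomRings(i) > 1 for i in ring):
            continue
        ring_set = set(ring)
        oxygens = [i for i in ring if mol.GetAtomWithIdx(i).GetAtomicNum() == 8]
        if len(oxygens) != 1:
            continue
        carbons = [mol.GetAtomWithIdx(i) for i in ring if i not in oxygens]
        if any(a.GetAtomicNum() != 6 or a.GetHybridization() != Chem.HybridizationType.SP3
               for a in carbons):
            continue
        exo_oxygens = set()
        for i in ring:
            atom = mol.GetAtomWithIdx(i)
            for nb in atom.GetNeighbors():
                j = nb.GetIdx()
                if j in ring_set or nb.GetAtomicNum() != 8 or nb.IsInRing():
                    continue
                bond = mol.GetBondBetweenAtoms(i, j)
                if bond.GetBondType() == Chem.BondType.SINGLE:
                    exo_oxygens.add(j)
        if len(exo_oxygens) / len(ring) < cfg["exocyclic_oxygen_ratio_min"]:
            continue
        atoms = frozenset(ring_set | exo_oxygens)
        removal = _removal_set(mol, SugarHit(SugarKind.CIRCULAR, atoms, False))
        terminal = _is_terminal(mol, removal, cfg["min_aglycone_heavy_atoms"])
        hits.append(SugarHit(SugarKind.CIRCULAR, atoms, terminal))
    return hits


def detect_linear_sugars(mol: Chem.Mol, settings: Optional[dict] = None) -> list[SugarHit]:
    """Find linear sugar moieties: acyclic 3–7 carbon chains, one oxygen
    substituent per chain carbon."""
    cfg = _settings(settings)
    candidates: dict[int, int] = {}  # chain carbon -> its oxygen
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.IsInRing():
            continue
        oxygens = [nb.GetIdx() for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 8]
        if len(oxygens) != 1:
            continue
        candidates[atom.GetIdx()] = oxygens[0]
    # connected components of candidate carbons via C-C bonds
    hits = []
    remaining = set(candidates)
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
        if not 3 <= len(component) <= 7:
            continue
        # chain, not branch: at most two in-component carbon neighbours
        def in_comp_degree(i: int) -> int:
            return sum(nb.GetIdx() in component for nb in mol.GetAtomWithIdx(i).GetNeighbors())
        if any(in_comp_degree(i) > 2 for i in component):
            continue
        atoms = frozenset(component | {candidates[i] for i in component})
        removal = _removal_set(mol, SugarHit(SugarKind.LINEAR, atoms, False))
        terminal = _is_terminal(mol, removal, cfg["min_aglycone_heavy_atoms"])
        hits.append(SugarHit(SugarKind.LINEAR, atoms, terminal))
    return hits


def remove_sugars(mol: Chem.Mol, settings: Optional[dict] = None) -> list[str]:
    """Iteratively delete sugar moieties; return the aglycone fragments
    (plus the removed sugars when ``return_sugars``).

    Returns an empty list when the whole molecule is sugar; sugar-free
    input is returned unchanged.
    """
    cfg = _settings(settings)
    current: Optional[Chem.Mol] = mol
    removed_sugars: list[str] = []
    while current is not None and current.GetNumAtoms() > 0:
        hits: list[SugarHit] = []
        if cfg["detect_circular"]:
            hits += detect_circular_sugars(current, cfg)
        if cfg["detect_linear"]:
            hits += detect_linear_sugars(current, cfg)
        if cfg["remove_only_terminal"]:
            hits = [h for h in hits if h.terminal]
        if not hits:
            break
        hit = min(hits, key=lambda h: min(h.atom_indices))
        removal = _removal_set(current, hit)
        removed_sugars += extract_fragments(current, removal)
        keep = set(range(current.GetNumAtoms())) - removal
        substantial = [
            s
            for s in extract_fragments(current, keep)
            if parse_smiles(s).GetNumHeavyAtoms() >= cfg["min_aglycone_heavy_atoms"]
        ]
        current = parse_smiles(".".join(substantial)) if substantial else None
    aglycone: list[str] = []
    if current is not None and current.GetNumAtoms() > 0:
        aglycone = [Chem.MolToSmiles(f) for f in Chem.GetMolFrags(current, asMols=True)]
    if cfg["return_sugars"]:
        aglycone += [canonicalise(s) for s in removed_sugars]
    return aglycone


@register
class SugarRemovalFragmenter(MoleculeFragmenter):
    """Deglycosylation: returns the aglycone (and optionally the sugars)."""

    identifier = "sugar-removal"
    setting_descriptors = (
        SettingDescriptor("detect_circular", ValueType.BOOLEAN, True,
                          "Detect furanose/pyranose-sized circular sugars."),
        SettingDescriptor("detect_linear", ValueType.BOOLEAN, False,
                          "Detect acyclic polyol/polyketo sugar chains."),
        SettingDescriptor("remove_only_terminal", ValueType.BOOLEAN, True,
                          "Only remove moieties whose removal leaves the "
                          "remainder connected."),
        SettingDescriptor("exocyclic_oxygen_ratio_min", ValueType.FLOAT, 0.5,
                          "Minimum exocyclic single-bonded oxygens per ring "
                          "atom for a ring to count as a sugar (0..1)."),
        SettingDescriptor("min_aglycone_heavy_atoms", ValueType.INTEGER, 5,
                          "Disconnected leftovers below this heavy-atom "
                          "count are discarded."),
        SettingDescriptor("return_sugars", ValueType.BOOLEAN, False,
                          "Also return the removed sugar moieties as "
                          "fragments."),
    )

    def fragment(self, mol: Chem.Mol) -> list[str]:
        if mol.GetNumAtoms() == 0:
            return []
        return remove_sugars(mol, self.settings)
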