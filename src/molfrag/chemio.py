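"""Structure I/O and canonicalisation.

All structure handling is built on RDKit.  The framework-wide canonical
form is RDKit canonical SMILES with one twist: fragments produced by
functional-group extraction may contain aromatic atoms outside rings
(the field-standard depiction of an aromatic attachment point, e.g. the
hydroxy-on-aromatic-carbon group ``[H]Oc``).  Such pseudo-SMILES cannot be
kekulised, so :func:`canonicalise` falls back to a partial sanitisation
that skips kekulisation and folds explicit hydrogens into hydrogen
counts.  Both a parsed exemplar string and a fragment cut out of a real
molecule then map to the same canonical key, which makes string equality
a sound deduplication criterion.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger

from .records import FragmentRecord, MoleculeRecord, MoleculeStatus

logger = logging.getLogger(__name__)

# RDKit logs every rejected line itself; the framework reports skips once,
# with line numbers, through its own logger.
RDLogger.DisableLog("rdApp.*")

_PARTIAL_SANITIZE = Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.AROMATIC: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}


class ChemIOError(Exception):
    """Fatal import/export failure (missing file, zero parsable entries)."""


class SmilesParseError(ValueError):
    """Raised by :func:`canonicalise` / :func:`parse_smiles`; carries the input."""

    def __init__(self, smiles: str, detail: str = "") -> None:
        self.smiles = smiles
        msg = f"unparsable SMILES: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string to a sanitised RDKit molecule.

    Fully sanitises where possible; fragment pseudo-SMILES with aromatic
    atoms outside rings are sanitised without kekulisation and have their
    explicit hydrogen atoms folded into hydrogen counts.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        return mol
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesParseError(smiles)
    try:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(mol, _PARTIAL_SANITIZE)
        mol = Chem.RemoveHs(mol, sanitize=False)
    except Exception as exc:  # valence errors etc.
        raise SmilesParseError(smiles, str(exc)) from None
    return mol


def canonicalise(smiles: str) -> str:
    """Return the framework-wide canonical form of ``smiles``.

    Deterministic and idempotent; two inputs denoting the same structure
    after aromaticity perception map to the same output.  Raises
    :class:`SmilesParseError` on unparsable input.
    """
    return Chem.MolToSmiles(parse_smiles(smiles))


def heavy_atom_count(smiles: str) -> int:
    """Number of non-hydrogen atoms in a (possibly pseudo-) SMILES."""
    return parse_smiles(smiles).GetNumHeavyAtoms()


# ---------------------------------------------------------------------------
# fragment extraction: the framework-wide cut-bond convention
# ---------------------------------------------------------------------------

def extract_fragments(mol: Chem.Mol, keep: Iterable[int]) -> list[str]:
    """Cut out the atoms in ``keep`` and return one canonical SMILES per
    connected component.

    Implements the framework-wide bond-cleavage convention: bonds to
    deleted atoms are cut without preserving any information and the open
    valences are saturated with hydrogen.  Aromatic systems wholly
    contained in the kept set stay aromatic; atoms whose ring was broken
    are de-aromatised and re-saturated.  Stereodescriptors that become
    meaningless at cut atoms are dropped.
    """
    keep = set(keep)
    if not keep:
        return []
    # hydrogen bookkeeping for cut bonds, recorded before deletion
    lost: dict[int, int] = {}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in keep) != (j in keep):
            k = i if i in keep else j
            lost[k] = lost.get(k, 0) + _BOND_ORDER.get(bond.GetBondType(), 1)
    prior_h = {i: mol.GetAtomWithIdx(i).GetTotalNumHs() for i in lost}
    was_aromatic = {i: mol.GetAtomWithIdx(i).GetIsAromatic() for i in keep}

    editable = Chem.RWMol(mol)
    for idx in sorted(set(range(mol.GetNumAtoms())) - keep, reverse=True):
        editable.RemoveAtom(idx)
    out = editable.GetMol()
    old_for_new = dict(enumerate(sorted(keep)))

    # de-aromatise atoms whose ring membership broke
    Chem.FastFindRings(out)
    ring_info = out.GetRingInfo()
    for atom in out.GetAtoms():
        if atom.GetIsAromatic() and not ring_info.NumAtomRings(atom.GetIdx()):
            atom.SetIsAromatic(False)
    for bond in out.GetBonds():
        if bond.GetBondType() == Chem.BondType.AROMATIC and not (
            bond.GetBeginAtom().GetIsAromatic() and bond.GetEndAtom().GetIsAromatic()
        ):
            bond.SetBondType(Chem.BondType.SINGLE)
            bond.SetIsAromatic(False)

    for atom in out.GetAtoms():
        old = old_for_new[atom.GetIdx()]
        dearomatised = was_aromatic[old] and not atom.GetIsAromatic()
        if dearomatised:
            # valence demand changed; let RDKit refill hydrogens
            atom.SetNumExplicitHs(0)
            atom.SetNoImplicit(False)
            atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        elif old in lost:
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(prior_h[old] + lost[old])
            atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)

    out.UpdatePropertyCache(strict=False)
    try:
        Chem.SanitizeMol(out)
        Chem.AssignStereochemistry(out, cleanIt=True, force=True)
    except Exception:
        Chem.SanitizeMol(out, _PARTIAL_SANITIZE)
    frags = Chem.GetMolFrags(out, asMols=True, sanitizeFrags=False)
    return [Chem.MolToSmiles(f) for f in frags]


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

@dataclass
class ImportResult:
    """Outcome of a file import: records plus skip bookkeeping.

    ``skipped + len(records)`` equals the number of candidate entries in
    the input (a detected header line is not a candidate).
    """

    records: list[MoleculeRecord]
    skipped: int = 0
    skipped_entries: list[int] = field(default_factory=list)
    header_skipped: bool = False

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_smiles_file(
    path: str | Path,
    separator: Optional[str] = None,
    name_column: int = 1,
) -> ImportResult:
    """Import a SMILES text file: one structure per line, first token the
    SMILES, optional second token the name.

    A single leading header line is auto-detected by first-token parse
    failure and skipped.  Unparsable lines are skipped, counted and
    logged; zero parsable lines is a fatal error.
    """
    path = Path(path)
    if not path.is_file():
        raise ChemIOError(f"no such file: {path}")
    records: list[MoleculeRecord] = []
    skipped: list[int] = []
    header_skipped = False
    first_data_line = True
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            tokens = line.split(separator) if separator else line.split()
            smiles = tokens[0]
            try:
                canonical = canonicalise(smiles)
            except SmilesParseError:
                if first_data_line:
                    header_skipped = True
                    logger.info("%s:%d: header line detected and skipped", path, lineno)
                else:
                    skipped.append(lineno)
                    logger.warning("%s:%d: unparsable SMILES %r, line skipped", path, lineno, smiles)
                first_data_line = False
                continue
            first_data_line = False
            if len(tokens) > name_column and tokens[name_column]:
                name = tokens[name_column]
            else:
                name = f"Molecule_{len(records)}"
            records.append(
                MoleculeRecord(
                    record_id=len(records),
                    name=name,
                    input_smiles=smiles,
                    canonical_smiles=canonical,
                )
            )
    if not records:
        raise ChemIOError(
            f"{path}: no parsable SMILES lines ({len(skipped)} line(s) failed: {skipped})"
        )
    if skipped:
        logger.warning("%s: skipped %d unparsable line(s)", path, len(skipped))
    return ImportResult(records, skipped=len(skipped), skipped_entries=skipped,
                        header_skipped=header_skipped)


def read_sdf(path: str | Path, name_property: Optional[str] = None) -> ImportResult:
    """Import an SD file or single Molfile (V2000 or V3000).

    Names are taken from the title line, else from ``name_property`` when
    given, else auto-generated.  Invalid blocks are skipped and logged;
    an unreadable or empty file is a fatal error.
    """
    path = Path(path)
    if not path.is_file():
        raise ChemIOError(f"no such file: {path}")
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    except OSError as exc:
        raise ChemIOError(f"{path}: not a readable SD file ({exc})") from None
    records: list[MoleculeRecord] = []
    skipped: list[int] = []
    for block_no, mol in enumerate(supplier):
        if mol is None:
            skipped.append(block_no)
            logger.warning("%s: block %d unreadable, skipped", path, block_no)
            continue
        canonical = Chem.MolToSmiles(mol)
        name = ""
        if mol.HasProp("_Name"):
            name = mol.GetProp("_Name").strip()
        if not name and name_property and mol.HasProp(name_property):
            name = mol.GetProp(name_property).strip()
        if not name:
            name = f"Molecule_{len(records)}"
        records.append(
            MoleculeRecord(
                record_id=len(records),
                name=name,
                input_smiles=canonical,
                canonical_smiles=canonical,
            )
        )
    if not records:
        raise ChemIOError(f"{path}: no valid structure blocks ({len(skipped)} failed)")
    if skipped:
        logger.warning("%s: skipped %d unreadable block(s)", path, len(skipped))
    return ImportResult(records, skipped=len(skipped), skipped_entries=skipped)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_fragments_csv(fragments: Sequence[FragmentRecord], path: str | Path) -> None:
    """Write the deduplicated fragment table as CSV (RFC-4180, UTF-8).

    Columns: rank, fragment_smiles, frequency, molecule_frequency,
    sample_parent_name; rows in rank order (frequency descending).
    """
    if not fragments:
        raise ValueError("empty fragment list")
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["rank", "fragment_smiles", "frequency", "molecule_frequency", "sample_parent_name"]
        )
        for rank, frag in enumerate(fragments, start=1):
            writer.writerow(
                [rank, frag.canonical_smiles, frag.frequency, frag.molecule_frequency,
                 frag.sample_parent_name]
            )


def write_items_csv(
    molecules: Sequence[MoleculeRecord], run_name: str, path: str | Path
) -> None:
    """Write the per-molecule item table: one row per (molecule, fragment).

    Columns: molecule_name, molecule_smiles, fragment_smiles,
    count_in_molecule.
    """
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["molecule_name", "molecule_smiles", "fragment_smiles", "count_in_molecule"])
        for record in molecules:
            for frag_smiles, count in record.run_results.get(run_name, []):
                writer.writerow([record.name, record.canonical_smiles, frag_smiles, count])


def write_fragments_sdf(fragments: Sequence[FragmentRecord], path: str | Path) -> None:
    """Write fragments as an SD file (V2000) with ``frequency``,
    ``molecule_frequency`` and ``sample_parent_name`` as SD properties.

    The authoritative canonical SMILES is carried in a ``fragment_smiles``
    property: molfiles cannot represent aromatic atoms outside rings, so
    for generalised functional-group pseudo-fragments the connection table
    alone underdetermines the fragment.
    """
    if not fragments:
        raise ValueError("empty fragment list")
    blocks: list[str] = []
    for frag in fragments:
        mol = parse_smiles(frag.canonical_smiles)
        mol.SetProp("_Name", frag.canonical_smiles)
        try:
            block = Chem.MolToMolBlock(mol)
        except Exception:
            block = Chem.MolToMolBlock(mol, kekulize=False)
        props = {
            "fragment_smiles": frag.canonical_smiles,
            "frequency": frag.frequency,
            "molecule_frequency": frag.molecule_frequency,
            "sample_parent_name": frag.sample_parent_name,
        }
        for key, value in props.items():
            block += f">  <{key}>\n{value}\n\n"
        blocks.append(block + "$$$$\n")
    Path(path).write_text("".join(blocks), encoding="utf-8")


def write_molecules_sdf(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write molecule records as a plain SD file (used by the fixture panel)."""
    blocks = []
    for record in records:
        mol = parse_smiles(record.canonical_smiles)
        mol.SetProp("_Name", record.name)
        try:
            block = Chem.MolToMolBlock(mol)
        except Exception:
            block = Chem.MolToMolBlock(mol, kekulize=False)
        blocks.append(block + "$$$$\n")
    Path(path).write_text("".join(blocks), encoding="utf-8")
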