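"""Core data model: molecules, fragments and fragmentation runs.

The framework keeps canonical SMILES as the only retained structural
information; RDKit molecule objects are created on demand from these
strings.  Every deduplication, frequency count and file export keys on the
canonical string form produced by :func:`molfrag.chemio.canonicalise`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class MoleculeStatus(enum.Enum):
    """Outcome of a molecule in a fragmentation run."""

    OK = "OK"
    FILTERED = "FILTERED"
    PREPROCESSED = "PREPROCESSED"
    FAILED = "FAILED"


@dataclass
class MoleculeRecord:
    """An imported structure.

    Attributes
    ----------
    record_id:
        0-based import order among successfully parsed inputs; unique
        within one imported set and used as the stable molecule key.
    name:
        Display name; taken from the input file where available, else
        auto-generated as ``Molecule_<index>``.  Not required to be unique.
    input_smiles:
        The structure string as read (for SDF input, the canonical SMILES
        of the parsed block).
    canonical_smiles:
        Framework-wide canonical form; parses to a valid structure
        whenever ``status != FAILED``.
    status:
        Outcome of the most recent fragmentation run this record took
        part in (``OK`` right after import).
    status_reason:
        Human-readable reason for FILTERED/FAILED statuses.
    run_results:
        Map from run name to the list of ``(fragment_canonical_smiles,
        count_in_molecule)`` pairs produced for this molecule; every count
        is >= 1.
    """

    record_id: int
    name: str
    input_smiles: str
    canonical_smiles: str
    status: MoleculeStatus = MoleculeStatus.OK
    status_reason: Optional[str] = None
    run_results: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


@dataclass
class FragmentRecord:
    """A deduplicated fragment with its frequencies over one run.

    ``frequency`` counts total occurrences over all molecules,
    ``molecule_frequency`` the number of distinct input molecules the
    fragment occurs in; ``1 <= molecule_frequency <= frequency``.  The
    sample parent is one containing molecule drawn by a seeded generator.
    """

    canonical_smiles: str
    frequency: int
    molecule_frequency: int
    sample_parent_id: int
    sample_parent_name: str = ""


@dataclass
class PipelineSpec:
    """Ordered list of ``(fragmenter identifier, settings overrides)`` stages."""

    stages: list[tuple[str, dict]]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("a pipeline needs at least one stage")

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class MoleculeRunResult:
    """Per-molecule outcome inside a :class:`FragmentationRun`."""

    status: MoleculeStatus
    reason: Optional[str]
    fragments: dict[str, int]  # canonical smiles -> count in this molecule


@dataclass
class FragmentationRun:
    """One execution (single algorithm or pipeline) with aggregated results."""

    run_name: str
    stages: PipelineSpec
    settings_snapshot: dict[str, dict]
    molecule_results: dict[int, MoleculeRunResult]
    fragments: list[FragmentRecord]
    seed: int = 0

    @property
    def summary(self) -> dict[str, int]:
        statuses = [r.status for r in self.molecule_results.values()]
        n_filtered = sum(s is MoleculeStatus.FILTERED for s in statuses)
        n_failed = sum(s is MoleculeStatus.FAILED for s in statuses)
        return {
            "imported": len(statuses),
            "fragmented": len(statuses) - n_filtered - n_failed,
            "filtered": n_filtered,
            "failed": n_failed,
            "distinct_fragments": len(self.fragments),
            "stages": len(self.stages),
        }
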