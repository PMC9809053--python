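"""The fragmenter plugin contract.

Every fragmentation algorithm implements :class:`MoleculeFragmenter`:
typed, documented settings (:class:`SettingDescriptor`), an input filter,
a preprocessing step and the fragmentation operation itself.  For every
structure exactly one of three things happens: it is filtered (with a
reason), it fails (logged, run continues), or it yields a — possibly
empty — fragment list.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Type

from rdkit import Chem

logger = logging.getLogger(__name__)


class ValueType(enum.Enum):
    BOOLEAN = "boolean"
    INTEGER = "integer"
    FLOAT = "float"
    STRING = "string"
    ENUM = "enum"


_TRUE = {"true", "1", "yes", "on"}
_FALSE = {"false", "0", "no", "off"}


@dataclass(frozen=True)
class SettingDescriptor:
    """A typed, documented, persistable algorithm setting.

    The descriptor drives CLI ``--set`` parsing, validation and the
    line-based settings files; ``description`` is the tooltip text.
    """

    key: str
    value_type: ValueType
    default: Any
    description: str = ""
    allowed: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.value_type is ValueType.ENUM:
            if not self.allowed:
                raise ValueError(f"{self.key}: ENUM settings need an allowed list")
            if self.default not in self.allowed:
                raise ValueError(f"{self.key}: default {self.default!r} not in allowed values")
        else:
            self.validate(self.default)

    def validate(self, value: Any) -> Any:
        """Coerce and validate ``value``; raises ValueError when invalid."""
        vt = self.value_type
        if vt is ValueType.BOOLEAN:
            if isinstance(value, bool):
                return value
            if isinstance(value, str):
                low = value.strip().lower()
                if low in _TRUE:
                    return True
                if low in _FALSE:
                    return False
            raise ValueError(f"{self.key}: expected a boolean, got {value!r}")
        if vt is ValueType.INTEGER:
            if isinstance(value, bool):
                raise ValueError(f"{self.key}: expected an integer, got {value!r}")
            try:
                return int(value)
            except (TypeError, ValueError):
                raise ValueError(f"{self.key}: expected an integer, got {value!r}") from None
        if vt is ValueType.FLOAT:
            try:
                return float(value)
            except (TypeError, ValueError):
                raise ValueError(f"{self.key}: expected a number, got {value!r}") from None
        if vt is ValueType.ENUM:
            value = str(value)
            if value not in self.allowed:
                raise ValueError(
                    f"{self.key}: {value!r} is not one of {', '.join(map(str, self.allowed))}"
                )
            return value
        return str(value)


class MoleculeFragmenter:
    """Base class of the fragmenter plugin contract.

    Subclasses define ``identifier``, a list of :class:`SettingDescriptor`
    and the three operations.  ``fragment`` is only invoked on structures
    for which ``should_filter`` is false, after ``preprocess``.
    """

    identifier: str = ""
    setting_descriptors: Sequence[SettingDescriptor] = ()

    def __init__(self, **overrides: Any) -> None:
        descriptors = {d.key: d for d in self.setting_descriptors}
        if len(descriptors) != len(self.setting_descriptors):
            raise ValueError(f"{self.identifier}: duplicate setting keys")
        self.settings: dict[str, Any] = {d.key: d.default for d in self.setting_descriptors}
        for key, value in overrides.items():
            if key not in descriptors:
                raise ValueError(
                    f"{self.identifier}: unknown setting {key!r} "
                    f"(known: {', '.join(descriptors) or 'none'})"
                )
            self.settings[key] = descriptors[key].validate(value)

    # -- contract ----------------------------------------------------------
    def should_filter(self, mol: Chem.Mol) -> tuple[bool, str]:
        """Return ``(True, reason)`` when the structure must be excluded
        from this run.  Total: never raises."""
        return False, ""

    def preprocess(self, mol: Chem.Mol) -> Optional[Chem.Mol]:
        """Return a structure satisfying the algorithm's preconditions, or
        ``None`` to demote the molecule to FILTERED."""
        return mol

    def fragment(self, mol: Chem.Mol) -> list[str]:
        """Return the fragment list as canonical SMILES; duplicates encode
        per-molecule multiplicity.  An empty list is legal."""
        raise NotImplementedError


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Type[MoleculeFragmenter]] = {}


def register(cls: Type[MoleculeFragmenter]) -> Type[MoleculeFragmenter]:
    """Class decorator adding a fragmenter to the global registry."""
    if not cls.identifier:
        raise ValueError("fragmenter classes need a non-empty identifier")
    _REGISTRY[cls.identifier] = cls
    return cls


def registered_fragmenters() -> list[str]:
    return sorted(_REGISTRY)


def get_fragmenter(identifier: str, **overrides: Any) -> MoleculeFragmenter:
    """Instantiate a registered fragmenter with validated setting overrides."""
    try:
        cls = _REGISTRY[identifier]
    except KeyError:
        raise KeyError(
            f"unknown fragmenter {identifier!r}; registered: "
            f"{', '.join(registered_fragmenters())}"
        ) from None
    return cls(**overrides)


# ---------------------------------------------------------------------------
# shared preprocessing helpers
# ---------------------------------------------------------------------------

def neutralise_charges(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Neutralise formal charges where hydrogen addition/removal permits.

    Negatively charged atoms gain hydrogens, positively charged atoms
    bearing at least one hydrogen lose one per unit charge.  Returns
    ``None`` when a charge cannot be neutralised this way (e.g. a
    quaternary ammonium), signalling demotion to FILTERED.
    """
    if all(a.GetFormalCharge() == 0 for a in mol.GetAtoms()):
        return mol
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        charge = atom.GetFormalCharge()
        if charge == 0:
            continue
        if charge < 0:
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - charge)
            atom.SetFormalCharge(0)
        else:
            if atom.GetTotalNumHs() < charge:
                return None
            atom.SetNoImplicit(True)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() - charge)
            atom.SetFormalCharge(0)
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out
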