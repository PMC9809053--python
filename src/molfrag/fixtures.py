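"""Hand-curated toy-molecule panel with hand-derived expected fragments.

The panel makes every algorithm testable without downloads.  Expected
fragment multisets were derived by applying each algorithm's stated
rules by hand (and cross-checked against an independent brute-force
marking oracle in the test suite); they are written as plain hand
notation and canonicalised at load time, never produced by running the
fragmenters themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .chemio import canonicalise, write_molecules_sdf
from .records import MoleculeRecord

#: Sentinel expectation: the fragmenter filters this molecule out.
FILTERED = "FILTERED"


@dataclass
class FixtureCase:
    """One panel molecule with expected canonical fragment multisets.

    ``expected`` maps a fragmenter identifier (under its default
    settings) to either the sorted tuple of expected canonical fragment
    SMILES or the :data:`FILTERED` sentinel.
    """

    name: str
    smiles: str
    expected: dict[str, tuple[str, ...] | str] = field(default_factory=dict)


def _case(name: str, smiles: str, **expected) -> FixtureCase:
    resolved: dict[str, tuple[str, ...] | str] = {}
    for key, value in expected.items():
        key = key.replace("_", "-")
        if value == FILTERED:
            resolved[key] = FILTERED
        else:
            resolved[key] = tuple(sorted(canonicalise(s) for s in value))
    return FixtureCase(name=name, smiles=smiles, expected=resolved)


def toy_panel() -> list[FixtureCase]:
    """The deterministic fixture panel (22 molecules).

    Expectations are for default settings: ertl-fg in generalized mode
    with remnants, sugar-removal circular/terminal-only/aglycone-only,
    scaffold in SCAFFOLD_ONLY mode.
    """
    return [
        _case("methane", "C", ertl_fg=("C",)),
        _case("hexane", "CCCCCC", ertl_fg=("CCCCCC",), sugar_removal=("CCCCCC",)),
        _case("ethanol", "CCO", ertl_fg=("CO", "CC")),
        _case("ethylene-glycol", "OCCO", ertl_fg=("CO", "CO", "CC")),
        _case("ethene", "C=C", ertl_fg=("C=C",)),
        # the paper's hydroxy-on-aromatic-carbon exemplar "[H]Oc"
        _case("phenol", "Oc1ccccc1", ertl_fg=("[H]Oc", "c1ccccc1")),
        _case("acetic-acid", "CC(=O)O", ertl_fg=("CC(=O)O", "C")),
        _case("methyl-acetate", "COC(C)=O", ertl_fg=("COC(C)=O", "C", "C")),
        _case("diethyl-ether", "CCOCC", ertl_fg=("COC", "CC", "CC")),
        _case("acetamide", "CC(N)=O", ertl_fg=("CC(N)=O", "C")),
        _case("benzene", "c1ccccc1", ertl_fg=("c1ccccc1",), scaffold=("c1ccccc1",)),
        _case("toluene", "Cc1ccccc1", ertl_fg=("Cc1ccccc1",), scaffold=("c1ccccc1",)),
        _case("anisole", "COc1ccccc1", ertl_fg=("cOC", "C", "c1ccccc1"),
              scaffold=("c1ccccc1",)),
        _case("diphenylmethane", "c1ccccc1Cc1ccccc1",
              scaffold=("c1ccccc1Cc1ccccc1",)),
        # three distinct rings in a row: cyclohexane - benzene - pyridine
        _case("three-ring-chain", "C1CCCCC1Cc1ccc(Cc2ccncc2)cc1",
              scaffold=("C1CCCCC1Cc1ccc(Cc2ccncc2)cc1",)),
        _case("glucopyranose", "OCC1OC(O)C(O)C(O)C1O", sugar_removal=()),
        _case("salicin", "OCc1ccccc1OC1OC(CO)C(O)C(O)C1O",
              sugar_removal=("OCc1ccccc1O",)),
        _case("glycerol", "OCC(O)CO", sugar_removal=("OCC(O)CO",)),
        _case("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
              sugar_removal=("Cn1cnc2c1c(=O)n(C)c(=O)n2C",)),
        _case("ethanolate", "CC[O-]", ertl_fg=("CO", "CC")),  # neutralised first
        _case("tetramethylammonium", "C[N+](C)(C)C", ertl_fg=FILTERED),
        _case("dimethylmercury", "C[Hg]C", ertl_fg=FILTERED),
    ]


def panel_records(panel: list[FixtureCase] | None = None) -> list[MoleculeRecord]:
    """The panel as importable molecule records."""
    panel = panel if panel is not None else toy_panel()
    return [
        MoleculeRecord(
            record_id=i,
            name=case.name,
            input_smiles=case.smiles,
            canonical_smiles=canonicalise(case.smiles),
        )
        for i, case in enumerate(panel)
    ]


def write_panel_files(directory: str | Path) -> dict[str, Path]:
    """Emit the panel as a SMILES file and an SD file; byte-stable."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = panel_records()
    smi_path = directory / "panel.smi"
    lines = [f"{r.input_smiles}\t{r.name}" for r in records]
    smi_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sdf_path = directory / "panel.sdf"
    write_molecules_sdf(records, sdf_path)
    return {"smiles": smi_path, "sdf": sdf_path}
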