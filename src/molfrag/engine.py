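"""Fragmentation orchestration: single runs, pipelines, aggregation,
settings persistence and histogram tables.

Molecule sets are partitioned into contiguous chunks, processed
independently and recombined in input order, so results are identical
for any thread count.  Fragments are deduplicated by canonical SMILES
and aggregated into frequency records; the "sample parent" of each
fragment is drawn by a run-level seeded generator, making every run
reproducible.
"""

from __future__ import annotations

import logging
import random
from concurrent.futures import ThreadPoolExecutor
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem

from . import chemio
from .fragmenter import MoleculeFragmenter, get_fragmenter
from .records import (
    FragmentRecord,
    FragmentationRun,
    MoleculeRecord,
    MoleculeRunResult,
    MoleculeStatus,
    PipelineSpec,
)

logger = logging.getLogger(__name__)


def _process_molecule(
    record: MoleculeRecord, fragmenter: MoleculeFragmenter
) -> MoleculeRunResult:
    """Apply filter -> preprocess -> fragment to one molecule; total."""
    try:
        mol = chemio.parse_smiles(record.canonical_smiles)
    except chemio.SmilesParseError as exc:
        return MoleculeRunResult(MoleculeStatus.FAILED, str(exc), {})
    filtered, reason = fragmenter.should_filter(mol)
    if filtered:
        logger.info("molecule %d (%s) filtered: %s", record.record_id, record.name, reason)
        return MoleculeRunResult(MoleculeStatus.FILTERED, reason, {})
    processed = fragmenter.preprocess(mol)
    if processed is None:
        reason = "preprocessing could not establish algorithm preconditions"
        logger.info("molecule %d (%s) filtered: %s", record.record_id, record.name, reason)
        return MoleculeRunResult(MoleculeStatus.FILTERED, reason, {})
    status = MoleculeStatus.OK
    if Chem.MolToSmiles(processed) != record.canonical_smiles:
        status = MoleculeStatus.PREPROCESSED
    try:
        fragments = fragmenter.fragment(processed)
    except Exception as exc:  # per-molecule isolation: log and continue
        logger.warning("molecule %d (%s) failed: %s", record.record_id, record.name, exc)
        return MoleculeRunResult(MoleculeStatus.FAILED, str(exc), {})
    counts = Counter(chemio.canonicalise(f) for f in fragments)
    return MoleculeRunResult(status, None, dict(counts))


def _chunks(items: Sequence, n: int) -> list[Sequence]:
    n = max(1, min(n, len(items)))
    size, extra = divmod(len(items), n)
    out, start = [], 0
    for i in range(n):
        end = start + size + (1 if i < extra else 0)
        out.append(items[start:end])
        start = end
    return out


def aggregate(
    per_molecule: dict[int, dict[str, int]],
    molecules_by_id: dict[int, MoleculeRecord],
    seed: int = 0,
) -> list[FragmentRecord]:
    """Group per-molecule fragment counts into frequency records.

    Frequency is the total count over all molecules, molecule frequency
    the number of distinct molecules; the sample parent is drawn by a
    seeded generator.  Sorted by frequency descending, ties by canonical
    SMILES ascending.
    """
    totals: Counter = Counter()
    containing: dict[str, set[int]] = {}
    for record_id, counts in per_molecule.items():
        for smiles, count in counts.items():
            totals[smiles] += count
            containing.setdefault(smiles, set()).add(record_id)
    rng = random.Random(seed)
    records = []
    for smiles in sorted(totals):
        parent_id = rng.choice(sorted(containing[smiles]))
        records.append(
            FragmentRecord(
                canonical_smiles=smiles,
                frequency=totals[smiles],
                molecule_frequency=len(containing[smiles]),
                sample_parent_id=parent_id,
                sample_parent_name=molecules_by_id[parent_id].name,
            )
        )
    records.sort(key=lambda r: (-r.frequency, r.canonical_smiles))
    return records


def run_single(
    molecules: Sequence[MoleculeRecord],
    fragmenter: MoleculeFragmenter | str,
    n_threads: int = 1,
    seed: int = 0,
    run_name: Optional[str] = None,
) -> FragmentationRun:
    """Fragment a molecule set with one algorithm.

    Raises ``ValueError`` on an empty input set; an all-filtered set
    completes with an empty fragment list and a warning.
    """
    if not molecules:
        raise ValueError("no input molecules")
    if n_threads < 1:
        raise ValueError("n_threads must be >= 1")
    if isinstance(fragmenter, str):
        fragmenter = get_fragmenter(fragmenter)
    run_name = run_name or fragmenter.identifier

    chunks = _chunks(list(molecules), n_threads)
    if len(chunks) > 1:
        with ThreadPoolExecutor(max_workers=len(chunks)) as pool:
            chunk_results = list(
                pool.map(lambda ch: [_process_molecule(r, fragmenter) for r in ch], chunks)
            )
    else:
        chunk_results = [[_process_molecule(r, fragmenter) for r in chunks[0]]]
    results: dict[int, MoleculeRunResult] = {}
    for chunk, outcomes in zip(chunks, chunk_results):
        for record, outcome in zip(chunk, outcomes):
            results[record.record_id] = outcome

    _record_results(molecules, results, run_name)
    fragments = aggregate(
        {i: r.fragments for i, r in results.items() if r.fragments},
        {m.record_id: m for m in molecules},
        seed=seed,
    )
    if not fragments:
        logger.warning("run %r produced no fragments", run_name)
    return FragmentationRun(
        run_name=run_name,
        stages=PipelineSpec([(fragmenter.identifier, dict(fragmenter.settings))]),
        settings_snapshot={fragmenter.identifier: dict(fragmenter.settings)},
        molecule_results=results,
        fragments=fragments,
        seed=seed,
    )


def run_pipeline(
    molecules: Sequence[MoleculeRecord],
    pipeline: PipelineSpec,
    n_threads: int = 1,
    seed: int = 0,
    run_name: Optional[str] = None,
) -> FragmentationRun:
    """Execute a multi-stage pipeline.

    Stage 1 consumes the input molecules; each later stage consumes every
    fragment emitted by the stage before it.  Fragments a mid-pipeline
    stage filters (or cannot process) pass through unchanged with a
    logged note, so fragment counts are conserved.  Final frequencies are
    traced back to the original input molecules.
    """
    if not molecules:
        raise ValueError("no input molecules")
    fragmenters = [get_fragmenter(ident, **overrides) for ident, overrides in pipeline.stages]
    run_name = run_name or "+".join(f.identifier for f in fragmenters)

    first = fragmenters[0]
    chunks = _chunks(list(molecules), n_threads)
    if len(chunks) > 1:
        with ThreadPoolExecutor(max_workers=len(chunks)) as pool:
            chunk_results = list(
                pool.map(lambda ch: [_process_molecule(r, first) for r in ch], chunks)
            )
    else:
        chunk_results = [[_process_molecule(r, first) for r in chunks[0]]]
    results: dict[int, MoleculeRunResult] = {}
    for chunk, outcomes in zip(chunks, chunk_results):
        for record, outcome in zip(chunk, outcomes):
            results[record.record_id] = outcome

    for stage in fragmenters[1:]:
        cache: dict[str, Optional[list[str]]] = {}
        for record_id, outcome in results.items():
            if not outcome.fragments:
                continue
            next_counts: Counter = Counter()
            for smiles, count in outcome.fragments.items():
                if smiles not in cache:
                    cache[smiles] = _fragment_or_none(stage, smiles)
                produced = cache[smiles]
                if produced is None:
                    next_counts[smiles] += count  # pass through unchanged
                else:
                    for frag in produced:
                        next_counts[frag] += count
            results[record_id] = MoleculeRunResult(
                outcome.status, outcome.reason, dict(next_counts)
            )

    _record_results(molecules, results, run_name)
    fragments = aggregate(
        {i: r.fragments for i, r in results.items() if r.fragments},
        {m.record_id: m for m in molecules},
        seed=seed,
    )
    return FragmentationRun(
        run_name=run_name,
        stages=pipeline,
        settings_snapshot={f.identifier: dict(f.settings) for f in fragmenters},
        molecule_results=results,
        fragments=fragments,
        seed=seed,
    )


def _fragment_or_none(stage: MoleculeFragmenter, smiles: str) -> Optional[list[str]]:
    """Fragment one intermediate structure; ``None`` means pass-through."""
    try:
        mol = chemio.parse_smiles(smiles)
    except chemio.SmilesParseError:
        logger.info("stage %s cannot parse %r; passed through", stage.identifier, smiles)
        return None
    filtered, reason = stage.should_filter(mol)
    if filtered:
        logger.info("stage %s filters %r (%s); passed through", stage.identifier, smiles, reason)
        return None
    processed = stage.preprocess(mol)
    if processed is None:
        logger.info("stage %s cannot preprocess %r; passed through", stage.identifier, smiles)
        return None
    try:
        return [chemio.canonicalise(f) for f in stage.fragment(processed)]
    except Exception as exc:
        logger.warning("stage %s failed on %r (%s); passed through", stage.identifier, smiles, exc)
        return None


def _record_results(
    molecules: Sequence[MoleculeRecord],
    results: dict[int, MoleculeRunResult],
    run_name: str,
) -> None:
    for record in molecules:
        outcome = results[record.record_id]
        record.status = outcome.status
        record.status_reason = outcome.reason
        record.run_results[run_name] = sorted(
            outcome.fragments.items(), key=lambda kv: (-kv[1], kv[0])
        )


# ---------------------------------------------------------------------------
# settings persistence: line-based text files
# ---------------------------------------------------------------------------

def persist_settings(fragmenter: MoleculeFragmenter, path: str | Path) -> None:
    """Write the fragmenter's settings as ``key=value`` lines."""
    lines = [f"# {fragmenter.identifier} settings"]
    for descriptor in fragmenter.setting_descriptors:
        lines.append(f"{descriptor.key}={fragmenter.settings[descriptor.key]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_settings(fragmenter: MoleculeFragmenter, path: str | Path) -> dict:
    """Read ``key=value`` lines into a validated settings map.

    Unknown keys and invalid values warn and fall back to the default;
    an unreadable file yields the defaults with a warning.
    """
    descriptors = {d.key: d for d in fragmenter.setting_descriptors}
    settings = {d.key: d.default for d in fragmenter.setting_descriptors}
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        logger.warning("cannot read settings file %s (%s); using defaults", path, exc)
        return settings
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition("=")
        key = key.strip()
        if not sep:
            logger.warning("%s:%d: malformed line %r ignored", path, lineno, line)
            continue
        if key not in descriptors:
            logger.warning("%s:%d: unknown setting %r ignored", path, lineno, key)
            continue
        try:
            settings[key] = descriptors[key].validate(value.strip())
        except ValueError as exc:
            logger.warning("%s:%d: %s; default kept", path, lineno, exc)
    return settings


# ---------------------------------------------------------------------------
# frequency analytics
# ---------------------------------------------------------------------------

def histogram_data(
    run: FragmentationRun, top_n: int, by: str = "frequency"
) -> pd.DataFrame:
    """Top-``top_n`` fragments by ``frequency`` or ``molecule_frequency``.

    Returns a two-column table sorted descending by the chosen measure
    (ties by canonical SMILES); ``top_n`` larger than the fragment count
    returns all fragments.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if by not in ("frequency", "molecule_frequency"):
        raise ValueError(f"unknown measure {by!r}")
    rows = sorted(
        ((f.canonical_smiles, getattr(f, by)) for f in run.fragments),
        key=lambda kv: (-kv[1], kv[0]),
    )[:top_n]
    return pd.DataFrame(rows, columns=["fragment_smiles", by])


# ---------------------------------------------------------------------------
# run export
# ---------------------------------------------------------------------------

def write_run_outputs(
    run: FragmentationRun,
    molecules: Sequence[MoleculeRecord],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write fragments CSV, items CSV, fragments SDF and a JSON summary."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fragments_csv": outdir / "fragments.csv",
        "items_csv": outdir / "items.csv",
        "fragments_sdf": outdir / "fragments.sdf",
        "summary": outdir / "summary.json",
    }
    if run.fragments:
        chemio.write_fragments_csv(run.fragments, paths["fragments_csv"])
        chemio.write_fragments_sdf(run.fragments, paths["fragments_sdf"])
    chemio.write_items_csv(molecules, run.run_name, paths["items_csv"])
    summary = dict(run.summary)
    summary["run_name"] = run.run_name
    summary["seed"] = run.seed
    summary["stage_identifiers"] = [ident for ident, _ in run.stages.stages]
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return paths
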