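"""Run orchestration: aggregation, pipelines, determinism, settings
persistence, histogram tables."""

import logging

import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from molfrag import (
    MoleculeStatus,
    PipelineSpec,
    canonicalise,
    get_fragmenter,
    histogram_data,
    load_settings,
    persist_settings,
    run_pipeline,
    run_single,
)
from molfrag.engine import aggregate
from molfrag.records import MoleculeRecord


def _records(*smiles_names):
    return [
        MoleculeRecord(i, name, smiles, canonicalise(smiles))
        for i, (smiles, name) in enumerate(smiles_names)
    ]


@pytest.fixture()
def diol_set():
    return _records(("CCO", "ethanol"), ("OCCO", "glycol"))


class TestRunSingle:
    def test_hydroxy_frequencies_on_ethanol_and_glycol(self, diol_set):
        run = run_single(diol_set, "ertl-fg", seed=0)
        hydroxy = next(f for f in run.fragments if f.canonical_smiles == "CO")
        assert hydroxy.frequency == 3          # one OH + two OH
        assert hydroxy.molecule_frequency == 2

    def test_frequency_conservation(self, diol_set):
        run = run_single(diol_set, "ertl-fg")
        total = sum(f.frequency for f in run.fragments)
        per_molecule = sum(
            count
            for record in diol_set
            for _, count in record.run_results[run.run_name]
        )
        assert total == per_molecule

    def test_thread_invariance(self, panel_mols):
        runs = [
            run_single(panel_mols, "ertl-fg", n_threads=n, seed=7) for n in (1, 2, 4)
        ]
        reference = runs[0].fragments
        for run in runs[1:]:
            assert run.fragments == reference

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no input"):
            run_single([], "ertl-fg")

    def test_all_filtered_set_completes_with_empty_fragments(self, caplog):
        metals = _records(("C[Hg]C", "hg"), ("C[Si](C)(C)C", "si"))
        with caplog.at_level(logging.WARNING, logger="molfrag.engine"):
            run = run_single(metals, "ertl-fg")
        assert run.fragments == []
        assert run.summary["filtered"] == 2
        assert any("no fragments" in r.message for r in caplog.records)

    def test_statuses_recorded_per_molecule(self):
        mols = _records(("CCO", "ok"), ("CC[O-]", "anion"),
                        ("C[N+](C)(C)C", "quat"), ("C[Hg]C", "metal"))
        run = run_single(mols, "ertl-fg")
        statuses = {m.name: run.molecule_results[m.record_id].status for m in mols}
        assert statuses["ok"] is MoleculeStatus.OK
        assert statuses["anion"] is MoleculeStatus.PREPROCESSED
        assert statuses["quat"] is MoleculeStatus.FILTERED
        assert statuses["metal"] is MoleculeStatus.FILTERED
        summary = run.summary
        assert summary["imported"] == summary["fragmented"] + summary["filtered"] + summary["failed"]


class TestAggregate:
    def test_grouping_and_rank_order(self):
        mols = {0: MoleculeRecord(0, "A", "C", "C"), 1: MoleculeRecord(1, "B", "C", "C")}
        records = aggregate({0: {"x": 1}, 1: {"x": 2, "y": 1}}, mols, seed=0)
        assert [(r.canonical_smiles, r.frequency, r.molecule_frequency) for r in records] == [
            ("x", 3, 2), ("y", 1, 1)
        ]

    def test_equal_frequency_ties_break_by_canonical_key(self):
        mols = {0: MoleculeRecord(0, "A", "C", "C")}
        records = aggregate({0: {"b": 1, "a": 1}}, mols, seed=0)
        assert [r.canonical_smiles for r in records] == ["a", "b"]

    def test_sample_parent_reproducible_for_fixed_seed(self):
        mols = {i: MoleculeRecord(i, f"m{i}", "C", "C") for i in range(10)}
        counts = {i: {"x": 1} for i in range(10)}
        first = aggregate(counts, mols, seed=3)[0].sample_parent_id
        assert all(
            aggregate(counts, mols, seed=3)[0].sample_parent_id == first for _ in range(3)
        )

    @hyp_settings(derandomize=True, max_examples=60)
    @given(
        data=st.dictionaries(
            st.integers(0, 6),
            st.dictionaries(st.sampled_from(["a", "b", "c", "d"]),
                            st.integers(1, 5), min_size=1),
            min_size=1,
        ),
        seed=st.integers(0, 2**16),
    )
    def test_aggregate_invariants(self, data, seed):
        mols = {i: MoleculeRecord(i, f"m{i}", "C", "C") for i in data}
        records = aggregate(data, mols, seed=seed)
        total = sum(sum(c.values()) for c in data.values())
        assert sum(r.frequency for r in records) == total
        for r in records:
            assert 1 <= r.molecule_frequency <= r.frequency
            assert r.molecule_frequency <= len(data)
            # sample parent actually contains the fragment
            assert r.canonical_smiles in data[r.sample_parent_id]
        freqs = [r.frequency for r in records]
        assert freqs == sorted(freqs, reverse=True)


class TestPipeline:
    def test_anisole_pipeline_produces_aliphatic_hydroxy_group(self):
        mols = _records(("COc1ccccc1", "anisole"))
        spec = PipelineSpec([
            ("sugar-removal", {}),
            ("scaffold", {"fragmentation_type": "SIDE_CHAINS_ONLY"}),
            ("ertl-fg", {}),
        ])
        run = run_pipeline(mols, spec)
        assert canonicalise("CO") in {f.canonical_smiles for f in run.fragments}

    def test_single_stage_pipeline_equals_run_single(self, panel_mols):
        single = run_single(panel_mols, "ertl-fg", seed=5, run_name="r")
        import copy
        fresh = copy.deepcopy(panel_mols)
        piped = run_pipeline(fresh, PipelineSpec([("ertl-fg", {})]), seed=5, run_name="r")
        assert piped.fragments == single.fragments
        assert {i: r.status for i, r in piped.molecule_results.items()} == {
            i: r.status for i, r in single.molecule_results.items()
        }

    def test_sugar_free_molecule_passes_identity_stage(self):
        mols = _records(("Cn1cnc2c1c(=O)n(C)c(=O)n2C", "caffeine"))
        run = run_pipeline(mols, PipelineSpec([("sugar-removal", {})]))
        assert [(f.canonical_smiles, f.frequency) for f in run.fragments] == [
            (canonicalise("Cn1cnc2c1c(=O)n(C)c(=O)n2C"), 1)
        ]

    def test_filtered_fragment_passes_through_mid_pipeline(self):
        # stage 2 cannot accept the organometallic: it passes through
        # unchanged instead of vanishing, conserving counts
        mols = _records(("C[Hg]C", "organometallic"))
        spec = PipelineSpec([("sugar-removal", {}), ("ertl-fg", {})])
        run = run_pipeline(mols, spec)
        assert [(f.canonical_smiles, f.frequency) for f in run.fragments] == [
            (canonicalise("C[Hg]C"), 1)
        ]

    def test_molecule_frequency_traced_to_original_molecules(self):
        # two diols -> four identical hydroxy side products via scaffold;
        # molecule_frequency must count original molecules, not fragments
        mols = _records(("OCc1ccccc1CO", "diol-xylene"), ("OCc1ccccc1", "benzylalc"))
        spec = PipelineSpec([
            ("scaffold", {"fragmentation_type": "SIDE_CHAINS_ONLY"}),
            ("ertl-fg", {}),
        ])
        run = run_pipeline(mols, spec)
        hydroxy = next(f for f in run.fragments if f.canonical_smiles == "CO")
        assert hydroxy.frequency == 3
        assert hydroxy.molecule_frequency == 2

    def test_unknown_fragmenter_id_is_fatal(self, diol_set):
        with pytest.raises(KeyError):
            run_pipeline(diol_set, PipelineSpec([("nope", {})]))

    def test_conservation_through_multistage_pipeline(self, panel_mols):
        spec = PipelineSpec([
            ("sugar-removal", {}),
            ("scaffold", {"fragmentation_type": "SIDE_CHAINS_ONLY"}),
            ("ertl-fg", {}),
        ])
        run = run_pipeline(panel_mols, spec)
        total = sum(f.frequency for f in run.fragments)
        per_molecule = sum(
            count for r in run.molecule_results.values() for count in r.fragments.values()
        )
        assert total == per_molecule


class TestSettingsPersistence:
    def test_round_trip_identity(self, tmp_path):
        for identifier in ("ertl-fg", "sugar-removal", "scaffold"):
            fragmenter = get_fragmenter(identifier)
            path = tmp_path / f"{identifier}.settings"
            persist_settings(fragmenter, path)
            assert load_settings(fragmenter, path) == fragmenter.settings

    def test_invalid_value_keeps_default_with_warning(self, tmp_path, caplog):
        path = tmp_path / "ertl-fg.settings"
        path.write_text("environment_mode=bogus\n")
        fragmenter = get_fragmenter("ertl-fg")
        with caplog.at_level(logging.WARNING, logger="molfrag.engine"):
            settings = load_settings(fragmenter, path)
        assert settings["environment_mode"] == "generalized"
        assert any("default kept" in r.message for r in caplog.records)

    def test_unknown_key_ignored_with_warning(self, tmp_path, caplog):
        path = tmp_path / "ertl-fg.settings"
        path.write_text("foo=1\nreturn_remnants=false\n")
        fragmenter = get_fragmenter("ertl-fg")
        with caplog.at_level(logging.WARNING, logger="molfrag.engine"):
            settings = load_settings(fragmenter, path)
        assert settings["return_remnants"] is False
        assert any("unknown setting" in r.message for r in caplog.records)

    def test_unreadable_file_yields_defaults(self, tmp_path, caplog):
        fragmenter = get_fragmenter("ertl-fg")
        with caplog.at_level(logging.WARNING, logger="molfrag.engine"):
            settings = load_settings(fragmenter, tmp_path / "absent.settings")
        assert settings == fragmenter.settings


class TestHistogram:
    def _run(self, panel_mols):
        return run_single(panel_mols, "ertl-fg", seed=0)

    def test_top_n_rows(self, panel_mols):
        run = self._run(panel_mols)
        assert len(run.fragments) >= 10
        table = histogram_data(run, top_n=10)
        assert len(table) == 10
        assert list(table.columns) == ["fragment_smiles", "frequency"]

    def test_top_n_larger_than_fragment_count_returns_all(self, panel_mols):
        run = self._run(panel_mols)
        table = histogram_data(run, top_n=10_000)
        assert len(table) == len(run.fragments)

    def test_molecule_frequency_measure_may_reorder(self, panel_mols):
        run = self._run(panel_mols)
        by_freq = histogram_data(run, top_n=5, by="frequency")
        by_mf = histogram_data(run, top_n=5, by="molecule_frequency")
        values = by_mf["molecule_frequency"].tolist()
        assert values == sorted(values, reverse=True)
        assert set(by_freq.columns) != set(by_mf.columns)

    def test_top_one(self):
        mols = _records(("OCCO", "glycol"))
        run = run_single(mols, "ertl-fg")
        table = histogram_data(run, top_n=1)
        assert table.iloc[0]["fragment_smiles"] == "CO"
        assert table.iloc[0]["frequency"] == 2
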