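import numpy as np
import pytest

from readbridge.fixtures import (
    FixtureConfig,
    generate_events,
    generate_mapping_tables,
    generate_ontologies,
    generate_quality_labels,
    generate_snomed_tables,
    inflation_scenario,
    write_fixture_dir,
)
from readbridge.pipeline import RefinementStrategy, apply_flag_refinement, map_via_lookups
from readbridge.stats import QualityCategory, prevalence_count
from readbridge.terminology import CodeSystem


def test_config_validation():
    with pytest.raises(ValueError):
        FixtureConfig(disease_fraction=1.5)
    with pytest.raises(ValueError):
        FixtureConfig(flag_mix=(0.5, 0.5, 0, 0, 0, 0.1))


class TestOntologies:
    def test_deterministic_under_seed(self):
        a = generate_ontologies(FixtureConfig(seed=42))
        b = generate_ontologies(FixtureConfig(seed=42))
        for onto_a, onto_b in zip(a, b):
            assert list(onto_a.concepts) == list(onto_b.concepts)
            assert [c.description for c in onto_a] == [c.description for c in onto_b]

    def test_disease_fraction_one_gives_all_chapter_codes(self):
        read2, read3, _ = generate_ontologies(
            FixtureConfig(disease_fraction=1.0, n_read_codes=40, seed=1)
        )
        for onto in (read2, read3):
            assert all("A" <= c.code[0] <= "Z" for c in onto)

    def test_icd10_leaf_count_and_shape(self):
        cfg = FixtureConfig(n_icd10=50, seed=2)
        _, _, icd10 = generate_ontologies(cfg)
        leaves = [c for c in icd10 if c.parent_code is not None]
        categories = [c for c in icd10 if c.parent_code is None]
        assert len(leaves) == 50
        assert all(len(c.code) == 3 for c in categories)
        assert all(len(c.code) == 4 for c in leaves)
        icd10.validate()  # no dangling parents

    def test_read_codes_are_dot_padded_five_chars(self):
        read2, read3, _ = generate_ontologies(FixtureConfig(seed=3))
        for onto in (read2, read3):
            assert all(len(c.code) == 5 for c in onto)


class TestMappingTables:
    def test_zero_error_rate_gives_clean_gold(self):
        cfg = FixtureConfig(injected_error_rate=0.0, seed=4)
        ontos = generate_ontologies(cfg)
        _, gold = generate_mapping_tables(cfg, ontos)
        assert all(not g.wrong_targets for g in gold.entries.values())

    def test_gold_covers_every_code_exactly_once(self):
        cfg = FixtureConfig(seed=5)
        read2, read3, icd10 = generate_ontologies(cfg)
        _, gold = generate_mapping_tables(cfg, (read2, read3, icd10))
        assert len(gold) == len(read2) + len(read3)
        assert set(gold.entries) == {c.code for c in read2} | {c.code for c in read3}

    def test_all_exact_flags_make_refined_equal_full(self):
        cfg = FixtureConfig(
            flag_mix=(1.0, 0, 0, 0, 0, 0), injected_error_rate=0.0, seed=6
        )
        ontos = generate_ontologies(cfg)
        entries, _ = generate_mapping_tables(cfg, ontos)
        codes = sorted({(e.source_code, e.source_version) for e in entries})
        records, _ = map_via_lookups(codes, entries)
        refined, report = apply_flag_refinement(
            records, entries, RefinementStrategy.REFINED
        )
        assert refined == records and not report.excluded_codes

    def test_injected_error_count_matches_gold_bookkeeping(self):
        cfg = FixtureConfig(injected_error_rate=0.3, seed=7)
        ontos = generate_ontologies(cfg)
        entries, gold = generate_mapping_tables(cfg, ontos)
        n_wrong_entries = sum(
            1
            for e in entries
            if e.target_code in gold[e.source_code].wrong_targets
        )
        n_wrong_gold = sum(len(g.wrong_targets) for g in gold.entries.values())
        assert n_wrong_entries == n_wrong_gold > 0

    def test_wrong_targets_come_from_unrelated_chapters(self):
        cfg = FixtureConfig(injected_error_rate=0.5, seed=8)
        ontos = generate_ontologies(cfg)
        _, gold = generate_mapping_tables(cfg, ontos)
        for g in gold.entries.values():
            for wrong in g.wrong_targets:
                assert all(wrong[0] != t[0] for t in g.true_targets)


class TestSnomedTables:
    def test_zero_inactive_rate_means_resolution_is_identity(self):
        cfg = FixtureConfig(inactive_snomed_rate=0.0, seed=9)
        registry, read3_map, _, _ = generate_snomed_tables(cfg, [f"X{i:03d}." for i in range(50)])
        assert all(c.active for c in registry.values())
        assert all(registry[cid].active for cid in read3_map.values())

    def test_rates_recovered_at_scale(self):
        cfg = FixtureConfig(
            inactive_snomed_rate=0.42, refset_missing_rate=0.434,
            snomed_missing_rate=18 / 790, seed=10,
        )
        codes = [f"X{i:04d}"[:5] for i in range(790)]
        registry, read3_map, refset, gold = generate_snomed_tables(cfg, codes)
        n_missing = sum(1 for g in gold.entries.values() if not g.has_lookup)
        n_inactive = sum(
            1 for cid in read3_map.values() if not registry[cid].active
        )
        n_mapped = len(read3_map)
        assert n_missing / 790 == pytest.approx(18 / 790, abs=0.015)
        assert n_inactive / n_mapped == pytest.approx(0.42, abs=0.05)
        refset_ids = {cid for cid, _ in refset}
        active_final = {
            cid if registry[cid].active else _follow(registry, cid)
            for cid in read3_map.values()
        }
        missing_frac = 1 - len(refset_ids) / len(active_final)
        assert missing_frac == pytest.approx(0.434, abs=0.05)

    def test_chains_are_short_and_acyclic(self):
        from readbridge.snomed import resolve_inactive

        cfg = FixtureConfig(inactive_snomed_rate=1.0, seed=11)
        registry, read3_map, _, _ = generate_snomed_tables(
            cfg, [f"Y{i:03d}." for i in range(40)]
        )
        for cid in read3_map.values():
            resolved, did = resolve_inactive(registry[cid], registry)
            assert resolved.active and did


def _follow(registry, cid):
    while not registry[cid].active:
        cid = registry[cid].replaced_by
    return cid


class TestEvents:
    def test_no_patients_no_events(self):
        cfg = FixtureConfig(n_patients=0, seed=12)
        assert generate_events(cfg, [("A....", CodeSystem.READ2)]) == []

    def test_single_code_prevalence_equals_patient_count(self):
        cfg = FixtureConfig(n_patients=20, events_per_patient=2, seed=13)
        events = generate_events(cfg, [("A....", CodeSystem.READ2)])
        records, _ = map_via_lookups([], [])
        from readbridge.io import MappingRecord

        mapping = [
            MappingRecord(
                read_code="A....",
                read_version=CodeSystem.READ2,
                targets=[("B069", CodeSystem.ICD10)],
            )
        ]
        assert prevalence_count(events, mapping, "B06") == 20

    def test_common_code_dominates_event_stream(self):
        cfg = FixtureConfig(n_patients=200, events_per_patient=3, seed=14)
        codes = [(f"A{i:03d}."[:5], CodeSystem.READ3) for i in range(20)]
        events = generate_events(cfg, codes, common_code="A000.")
        n_common = sum(1 for e in events if e.read_3 == "A000.")
        assert n_common / len(events) > 0.5

    def test_dates_within_coverage_window(self):
        import datetime as dt

        cfg = FixtureConfig(n_patients=30, seed=15)
        events = generate_events(cfg, [("A....", CodeSystem.READ2)])
        assert all(
            dt.date(1990, 1, 1) <= e.event_dt <= dt.date(2017, 12, 31)
            for e in events
        )


class TestQualityLabels:
    def test_rates_approximately_recovered(self):
        labels = generate_quality_labels(5000, 0.3, seed=16)
        frac = np.mean([1 if l.group.value == "IMPRECISE" else 0 for l in labels])
        assert frac == pytest.approx(0.3, abs=0.03)

    def test_zero_rate_gives_no_imprecise(self):
        labels = generate_quality_labels(500, 0.0, seed=17, multiple_rate=0.0)
        assert set(labels) == {QualityCategory.PERFECT}


class TestInflationScenario:
    def test_full_mapping_inflates_and_refined_recovers_truth(self):
        scenario = inflation_scenario(FixtureConfig(seed=18))
        records, _ = map_via_lookups(scenario["codes"], scenario["entries"])
        full_n = prevalence_count(scenario["events"], records, "E70")
        refined, _ = apply_flag_refinement(
            records, scenario["entries"], RefinementStrategy.REFINED
        )
        refined_n = prevalence_count(scenario["events"], refined, "E70")
        assert full_n == scenario["full_e70_patients"]
        assert refined_n == scenario["true_e70_patients"]
        assert full_n >= 10 * refined_n


def test_write_fixture_dir_is_byte_deterministic(tmp_path):
    cfg = FixtureConfig(n_read_codes=40, n_icd10=30, n_patients=20, seed=19)
    dir_a = write_fixture_dir(cfg, tmp_path / "a")
    dir_b = write_fixture_dir(cfg, tmp_path / "b")
    assert set(dir_a) == set(dir_b)
    for name in dir_a:
        assert dir_a[name].read_bytes() == dir_b[name].read_bytes()
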