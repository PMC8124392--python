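import pandas as pd
import pytest

from dubscreen import (
    SubstrateRecord,
    SubstrateStore,
    Thresholds,
    load_published_screen,
    records_from_results,
)
from tests.test_differential import make_result


@pytest.fixture
def published_store():
    store = SubstrateStore()
    store.ingest(load_published_screen(), "published_usp_screen")
    return store


class TestIngest:
    def test_published_screen_has_56_records(self, published_store):
        assert len(published_store) == 56

    def test_reingesting_same_experiment_is_error(self, published_store):
        with pytest.raises(ValueError, match="already ingested"):
            published_store.ingest(load_published_screen(), "published_usp_screen")

    def test_duplicate_dub_gene_pair_named(self):
        store = SubstrateStore()
        records = [SubstrateRecord("USP7", "RNF2", log2_fc=1.5),
                   SubstrateRecord("USP7", "RNF2", log2_fc=2.0)]
        with pytest.raises(ValueError, match="USP7/RNF2"):
            store.ingest(records, "e1")

    def test_empty_ingest(self):
        store = SubstrateStore()
        store.ingest([], "empty")
        assert len(store) == 0

    def test_all_records_stored_unfiltered(self):
        # sub-threshold evidence is kept; thresholds act only at query time
        store = SubstrateStore()
        store.ingest([SubstrateRecord("USP1", "WEAK", log2_fc=0.2, p_value=0.9,
                                      unique_peptides=1)], "e1")
        assert len(store) == 1
        assert store.query_by_dub("USP1") == []


class TestQueries:
    def test_usp7_defaults_six_candidates(self, published_store):
        records = published_store.query_by_dub("USP7")
        assert len(records) == 6
        assert records[0].gene_name == "TTK"

    def test_usp11_three_records_led_by_rps2(self, published_store):
        records = published_store.query_by_dub("USP11")
        assert [r.gene_name for r in records] == ["RPS2", "UBE2L3", "RPS7"]

    def test_usp9x_twenty_records_with_extremes(self, published_store):
        records = published_store.query_by_dub("USP9X")
        assert len(records) == 20
        assert records[0].gene_name == "RNF10" and records[0].log2_fc == 3.94
        assert records[-1].gene_name == "PDIA4" and records[-1].log2_fc == 1.00

    def test_usp7_at_fc_2_only_ttk(self, published_store):
        records = published_store.query_by_dub("USP7", Thresholds(min_abs_log2_fc=2))
        assert [r.gene_name for r in records] == ["TTK"]

    def test_rnf2_regulated_by_usp7_and_usp42(self, published_store):
        hits = published_store.query_by_substrate("RNF2")
        assert [dub for dub, _ in hits] == ["USP7", "USP42"]

    def test_pcna_regulated_by_usp1(self, published_store):
        hits = published_store.query_by_substrate("PCNA")
        assert [dub for dub, _ in hits] == ["USP1"]
        assert hits[0][1].log2_fc == 1.49

    def test_unknown_names_give_empty_with_notice(self, published_store):
        assert published_store.query_by_dub("OTUB1") == []
        assert published_store.last_notices
        assert published_store.query_by_substrate("NOSUCHGENE") == []

    def test_case_insensitive_matching(self, published_store):
        assert len(published_store.query_by_dub("usp7")) == 6
        assert published_store.query_by_substrate("rnf2")

    def test_published_records_pass_missing_field_filters_with_notice(self, published_store):
        published_store.query_by_dub("USP7")
        assert any("vacuously" in n for n in published_store.last_notices)

    def test_bidirectional_consistency(self, published_store):
        t = Thresholds(min_abs_log2_fc=1.5)
        for dub in published_store.dubs():
            for r in published_store.query_by_dub(dub, t):
                dubs_for_gene = [d for d, _ in
                                 published_store.query_by_substrate(r.gene_name, t)]
                assert dub in dubs_for_gene

    def test_results_shrink_as_thresholds_tighten(self, published_store):
        sizes = [len(published_store.query_by_dub("USP42", Thresholds(min_abs_log2_fc=fc)))
                 for fc in (1.0, 1.5, 2.0, 3.0, 5.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestThresholdPersistence:
    def test_set_then_query_uses_new_values(self, tmp_path):
        path = tmp_path / "store.sqlite"
        with SubstrateStore(path) as store:
            store.ingest(load_published_screen(), "pub")
            store.set_thresholds(Thresholds(min_abs_log2_fc=2))
        # thresholds survive reopening the file
        with SubstrateStore(path) as store:
            assert store.thresholds.min_abs_log2_fc == 2
            assert len(store.query_by_dub("USP7")) == 1

    def test_reset_restores_defaults(self, published_store):
        published_store.set_thresholds(Thresholds(min_abs_log2_fc=3))
        published_store.reset_thresholds()
        assert published_store.thresholds == Thresholds()
        assert len(published_store.query_by_dub("USP7")) == 6

    def test_direction_down_lists_reduced_ubiquitination(self):
        store = SubstrateStore()
        store.ingest(
            [SubstrateRecord("USP1", "UPGENE", log2_fc=2.0, p_value=0.01, unique_peptides=4),
             SubstrateRecord("USP1", "DOWNGENE", log2_fc=-1.5, p_value=0.01, unique_peptides=4)],
            "e1",
        )
        store.set_thresholds(Thresholds(direction="down"))
        assert [r.gene_name for r in store.query_by_dub("USP1")] == ["DOWNGENE"]


class TestExportVolcano:
    def test_export_reimport_round_trip(self, tmp_path, published_store):
        records = published_store.query_by_dub("USP9X")
        path = tmp_path / "usp9x.csv"
        published_store.export_csv(records, path)
        fresh = SubstrateStore()
        fresh.import_csv(path, "reimport")
        assert fresh.query_by_dub("USP9X") == records

    def test_empty_export_is_header_only(self, tmp_path, published_store):
        path = tmp_path / "empty.csv"
        published_store.export_csv([], path)
        lines = [l for l in path.read_text().splitlines() if l]
        assert len(lines) == 1 and lines[0].startswith("dub_name,")

    def test_volcano_includes_subthreshold_points(self):
        store = SubstrateStore()
        results = [make_result(gene_name=f"G{i}", log2_fc=0.1 * i, p_value=0.5)
                   for i in range(30)]
        store.ingest(records_from_results(results, "USP1"), "e1")
        points = store.volcano_for_dub("USP1")
        assert len(points) == 30
        assert not all(p["passes_thresholds"] for p in points)

    def test_pipeline_records_carry_glygly_positions(self):
        results = [make_result(row_key="P1", gene_name="G1")]
        records = records_from_results(results, "USP1", {"P1": [5, 12]})
        assert records[0].glygly_positions == (5, 12)
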