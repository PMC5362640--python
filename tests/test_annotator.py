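"""Annotation rule engine: product rules, profile-database cascade, COG
translation, feature emission and GenBank update semantics."""

import pytest

from prokannot.annotator import (
    CONSERVED_HYPOTHETICAL,
    UNKNOWN_PRODUCT,
    cascade_profile_search,
    decide_annotation,
    emit_features,
    load_cog_table,
    sanitize_product,
    translate_cog,
    update_genbank_annotation,
)
from prokannot.homology import HitClass, HomologyHit, ProfileHit
from prokannot.records import Feature, FormatError, GeneCall, GeneModel, SeqRecord


def _blast_hit(desc="DNA polymerase III subunit alpha [Escherichia coli]", e=1e-40):
    return HomologyHit(
        query_id="g1", subject_id="WP_000001.1", pct_identity=95.0, aln_length=100,
        mismatches=5, gap_opens=0, qstart=1, qend=100, sstart=1, send=100,
        evalue=e, bitscore=200.0, description=desc,
    )


def _tigr_hit(e=1e-30, gene="dnaE", desc="dnaE: DNA polymerase III, alpha subunit 2.7.7.7"):
    return ProfileHit(
        query_id="g1", family_accession="TIGR00594", family_name="dnaE",
        evalue=e, score=150.0, description=desc,
        ec_numbers=["2.7.7.7"], gene_name=gene,
    )


class TestDecideAnnotation:
    def test_no_analyses_unknown(self):
        d = decide_annotation(None, None, 1e-5)
        assert d.product == UNKNOWN_PRODUCT and d.source == "none"

    def test_blast_none_unknown(self):
        d = decide_annotation(HitClass(HitClass.NONE), None, 1e-5)
        assert d.product == UNKNOWN_PRODUCT

    def test_blast_above_only_conserved_hypothetical(self):
        d = decide_annotation(HitClass(HitClass.ABOVE_ONLY), None, 1e-5)
        assert d.product == CONSERVED_HYPOTHETICAL

    def test_blast_best_names_product(self):
        d = decide_annotation(HitClass(HitClass.BEST, _blast_hit()), None, 1e-5)
        assert d.product == "DNA polymerase III subunit alpha"
        assert d.source == "blast"

    def test_tigrfam_override(self):
        d = decide_annotation(
            HitClass(HitClass.BEST, _blast_hit()), [_tigr_hit()], 1e-5
        )
        assert d.source == "tigrfam"
        assert d.gene_name == "dnaE"
        assert d.product.startswith("DNA polymerase III, alpha subunit")
        assert d.ec_numbers == ["2.7.7.7"]

    def test_tigrfam_above_threshold_no_override(self):
        d = decide_annotation(
            HitClass(HitClass.BEST, _blast_hit()), [_tigr_hit(e=1e-3)], 1e-5
        )
        assert d.source == "blast"

    def test_ec_suppressed_without_flag(self):
        d = decide_annotation(None, [_tigr_hit()], 1e-5, add_ec=False)
        assert d.ec_numbers == []

    def test_gene_name_suppressed_without_preference_flag(self):
        d = decide_annotation(None, [_tigr_hit()], 1e-5, prefer_tigrfam_names=False)
        assert d.gene_name == ""

    def test_pure_function(self):
        args = (HitClass(HitClass.BEST, _blast_hit()), [_tigr_hit()], 1e-5)
        assert decide_annotation(*args) == decide_annotation(*args)


@pytest.mark.parametrize(
    "raw,clean",
    [
        ("sp|P12345|DPO3A_ECOLI DNA polymerase III alpha [E. coli]",
         "DNA polymerase III alpha"),
        ("WP_000001.1 ribosomal protein S12", "ribosomal protein S12"),
        ("plain product name", "plain product name"),
    ],
)
def test_sanitize_product(raw, clean):
    assert sanitize_product(raw) == clean


class CountingEngine:
    """Mock engine recording which databases were queried."""

    name = "mock"

    def __init__(self, results_by_db):
        self.results_by_db = results_by_db
        self.queried = []

    def search(self, queries, database_ref=None, params=None):
        self.queried.append(database_ref)
        return self.results_by_db.get(database_ref, [])


class TestCascade:
    Q = SeqRecord(id="g1", sequence="MKTAYIAK")

    def test_hit_in_first_db_stops_cascade(self):
        engine = CountingEngine({"pfam_a": [_tigr_hit(e=1e-30)]})
        used, results = cascade_profile_search(
            self.Q, [("pfam_a", "pfam_a"), ("pfam_b", "pfam_b")], engine, 1e-5
        )
        assert used == "pfam_a"
        assert engine.queried == ["pfam_a"]  # pfam_b never touched

    def test_no_hits_anywhere_all_retained(self):
        engine = CountingEngine({})
        used, results = cascade_profile_search(
            self.Q, [("a", "a"), ("b", "b")], engine, 1e-5
        )
        assert used is None and set(results) == {"a", "b"}
        assert engine.queried == ["a", "b"]

    def test_above_threshold_in_first_falls_through_to_second(self):
        engine = CountingEngine(
            {"a": [_tigr_hit(e=1e-3)], "b": [_tigr_hit(e=1e-30)]}
        )
        used, _ = cascade_profile_search(self.Q, [("a", "a"), ("b", "b")], engine, 1e-5)
        assert used == "b"

    def test_engine_failure_skips_database(self):
        class Flaky(CountingEngine):
            def search(self, queries, database_ref=None, params=None):
                if database_ref == "a":
                    raise RuntimeError("down")
                return super().search(queries, database_ref, params)

        engine = Flaky({"b": [_tigr_hit(e=1e-30)]})
        log = []
        used, _ = cascade_profile_search(
            self.Q, [("a", "a"), ("b", "b")], engine, 1e-5, log=log
        )
        assert used == "b" and log


class TestCogTranslation:
    def test_known_code(self):
        table = load_cog_table()
        rec = translate_cog("COG0592", table)
        assert "sliding clamp" in rec.descriptor
        assert rec.categories == "L"

    def test_unknown_code_passthrough_with_warning(self):
        table = load_cog_table()
        log = []
        rec = translate_cog("COG9999", table, log)
        assert rec.descriptor == "uncharacterized" and log

    def test_malformed_code_rejected(self):
        with pytest.raises(FormatError):
            translate_cog("not-a-cog", load_cog_table())

    def test_every_table_entry_translates_cleanly(self):
        table = load_cog_table()
        log = []
        for code in table:
            rec = translate_cog(code, table, log)
            assert rec.descriptor and rec.descriptor != "uncharacterized"
        assert log == []


def _decisions(model, product="widget protein"):
    from prokannot.annotator import AnnotationDecision

    return {
        c.gene_number: AnnotationDecision(
            gene_number=c.gene_number, product=product, source="blast"
        )
        for c in model
    }


class TestEmitFeatures:
    MODEL = GeneModel(
        [
            GeneCall(start=100, end=400, strand="+", caller_tag="x", gene_number=1),
            GeneCall(start=600, end=900, strand="-", caller_tag="x", gene_number=2),
        ]
    )

    def test_gene_cds_pairs_identical_locations(self):
        feats = emit_features(self.MODEL, _decisions(self.MODEL))
        assert len(feats) == 4
        assert [(f.key, f.start, f.end, f.strand) for f in feats[:2]] == [
            ("gene", 100, 400, "+"),
            ("CDS", 100, 400, "+"),
        ]
        assert feats[1].qualifier("product") == "widget protein"

    def test_gene_number_on_both_members(self):
        feats = emit_features(self.MODEL, _decisions(self.MODEL))
        assert feats[0].qualifier("gene_number") == feats[1].qualifier("gene_number") == "1"

    def test_analysis_features_follow_pair_in_start_order(self):
        analyses = {
            1: [
                Feature("Pfam_hit", 200, 300, "+"),
                Feature("Blast_hit", 120, 380, "+"),
            ]
        }
        feats = emit_features(self.MODEL, _decisions(self.MODEL), analyses)
        keys = [(f.key, f.start) for f in feats[:4]]
        assert keys == [("gene", 100), ("CDS", 100), ("misc_feature", 120), ("misc_feature", 200)]
        assert feats[2].qualifier("note") == "analysis:Blast_hit"

    def test_strict_keys_mode_preserves_analysis_keys(self):
        analyses = {1: [Feature("Blast_hit", 120, 380, "+")]}
        feats = emit_features(self.MODEL, _decisions(self.MODEL), analyses, strict_keys=True)
        assert feats[2].key == "Blast_hit"

    def test_colour_constant_per_key(self):
        analyses = {
            1: [Feature("Pfam_hit", 200, 300, "+")],
            2: [Feature("Pfam_hit", 700, 800, "-")],
        }
        feats = emit_features(self.MODEL, _decisions(self.MODEL), analyses)
        colours = {f.qualifier("colour") for f in feats if f.qualifier("note")}
        assert len(colours) == 1

    def test_missing_decision_rejected(self):
        with pytest.raises(ValueError, match="decision"):
            emit_features(self.MODEL, {1: _decisions(self.MODEL)[1]})


class TestUpdateGenbank:
    def _record(self):
        return SeqRecord(
            id="r",
            sequence="A" * 1000,
            features=[
                Feature("gene", 100, 400, "+", qualifiers=[("gene", "abc")]),
                Feature("CDS", 100, 400, "+", qualifiers=[("product", "manually curated name")]),
                Feature("Blast_hit", 120, 380, "+", qualifiers=[("note", "old blast")]),
                Feature("Pfam_hit", 150, 350, "+", qualifiers=[("note", "old pfam")]),
            ],
        )

    def test_empty_selection_unchanged(self):
        rec = self._record()
        out = update_genbank_annotation(rec, [], [])
        assert [(f.key, f.start, f.qualifiers) for f in out.features] == [
            (f.key, f.start, f.qualifiers) for f in rec.features
        ]

    def test_update_one_analysis_preserves_others(self):
        rec = self._record()
        new = [Feature("Pfam_hit", 160, 340, "+", qualifiers=[("note", "new pfam")])]
        out = update_genbank_annotation(rec, ["Pfam_hit"], new)
        blast = [f for f in out.features if f.key == "Blast_hit"]
        assert blast[0].qualifier("note") == "old blast"
        pfam = [f for f in out.features if f.key == "Pfam_hit"]
        assert pfam[0].qualifier("note") == "new pfam"

    def test_preserve_gene_cds_keeps_manual_product(self):
        rec = self._record()
        replacement = [
            Feature("CDS", 100, 400, "+", qualifiers=[("product", "automated name")])
        ]
        out = update_genbank_annotation(
            rec, [], [], preserve_gene_cds=True, new_gene_cds=replacement
        )
        cds = [f for f in out.features if f.key == "CDS"]
        assert cds[0].qualifier("product") == "manually curated name"

    def test_record_without_model_rejected(self):
        bare = SeqRecord(id="r", sequence="A" * 100)
        with pytest.raises(ValueError, match="gene model"):
            update_genbank_annotation(bare, [], [])
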