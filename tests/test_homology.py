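"""Tabular hit parsing, keyword filtering, best-hit classification, rRNA
extrapolation and the built-in deterministic protein searcher."""

from math import log

import pytest

from prokannot.homology import (
    HitClass,
    HomologyHit,
    NaiveEngine,
    classify_hits,
    extrapolate_rrna,
    keyword_filter,
    naive_search,
    parse_profile_tblout,
    parse_tabular_hits,
    write_tabular_hits,
)
from prokannot.records import FormatError, SeqRecord


def _hit(**kw):
    base = dict(
        query_id="q",
        subject_id="s",
        pct_identity=90.0,
        aln_length=100,
        mismatches=10,
        gap_opens=0,
        qstart=1,
        qend=100,
        sstart=1,
        send=100,
        evalue=1e-20,
        bitscore=200.0,
    )
    base.update(kw)
    return HomologyHit(**base)


class TestTabularIO:
    def test_empty_text(self):
        assert parse_tabular_hits("") == []

    def test_single_row_evalue_parsed(self):
        row = "q1\ts1\t98.50\t100\t1\t0\t1\t100\t5\t104\t1e-50\t190.1"
        hits = parse_tabular_hits(row)
        assert len(hits) == 1
        assert hits[0].evalue == 1e-50
        assert hits[0].subject_len is None

    def test_optional_columns(self):
        row = "q\ts\t90\t50\t5\t0\t1\t50\t1\t50\t1e-9\t80.0\t1500\tsome protein [Org]"
        hit = parse_tabular_hits(row)[0]
        assert hit.subject_len == 1500
        assert hit.description == "some protein [Org]"

    def test_short_row_rejected(self):
        with pytest.raises(FormatError, match="12"):
            parse_tabular_hits("q\ts\t90\t50")

    def test_bad_numeric_names_line(self):
        rows = "q\ts\t90\t50\t5\t0\t1\t50\t1\t50\t1e-9\t80.0\n" \
               "q\ts\tabc\t50\t5\t0\t1\t50\t1\t50\t1e-9\t80.0"
        with pytest.raises(FormatError, match="line 2"):
            parse_tabular_hits(rows)

    def test_round_trip_100_rows(self):
        hits = [
            _hit(query_id=f"q{i}", subject_id=f"s{i}", evalue=10.0 ** -i,
                 subject_len=100 + i, description=f"protein {i}")
            for i in range(100)
        ]
        back = parse_tabular_hits(write_tabular_hits(hits))
        assert len(back) == 100
        for a, b in zip(hits, back):
            assert (a.query_id, a.subject_id, a.qstart, a.qend) == (
                b.query_id, b.subject_id, b.qstart, b.qend
            )
            assert b.evalue == pytest.approx(a.evalue, rel=1e-2)

    def test_inverted_query_coordinates_rejected(self):
        with pytest.raises(ValueError, match="qstart"):
            _hit(qstart=100, qend=1)


class TestProfileTblout:
    def test_gene_name_and_ec_extracted(self):
        line = (
            "TIGR00594  TIGR00594  gene_3  -  1.2e-40  140.1  0.0  "
            "1.5e-40  139.0  0.0  1.0  1  0  0  1  1  1  1  "
            "polA: DNA polymerase I 2.7.7.7"
        )
        hits = parse_profile_tblout(line)
        assert hits[0].gene_name == "polA"
        assert hits[0].ec_numbers == ["2.7.7.7"]
        assert hits[0].evalue == 1.2e-40

    def test_comment_lines_skipped(self):
        assert parse_profile_tblout("# comment\n#\n") == []


class TestKeywordFilter:
    def test_empty_keywords_identity(self):
        hits = [_hit(description="hypothetical protein")]
        assert keyword_filter(hits, []) == hits

    def test_case_insensitive_substring(self):
        hits = [
            _hit(subject_id="a", description="Hypothetical protein X"),
            _hit(subject_id="b", description="DNA polymerase"),
        ]
        out = keyword_filter(hits, ["hypothetical"])
        assert [h.subject_id for h in out] == ["b"]

    def test_idempotent(self):
        hits = [_hit(description="putative thing"), _hit(description="real thing")]
        once = keyword_filter(hits, ["putative"])
        assert keyword_filter(once, ["putative"]) == once


class TestClassifyHits:
    def test_empty_is_none(self):
        assert classify_hits([], 1e-5).kind == HitClass.NONE

    def test_above_only(self):
        assert classify_hits([_hit(evalue=1e-3)], 1e-5).kind == HitClass.ABOVE_ONLY

    def test_best_is_argmin(self):
        hits = [_hit(subject_id="a", evalue=1e-10), _hit(subject_id="b", evalue=1e-30)]
        out = classify_hits(hits, 1e-5)
        assert out.kind == HitClass.BEST and out.hit.subject_id == "b"

    def test_permutation_invariant(self):
        hits = [
            _hit(subject_id=s, evalue=e, bitscore=b)
            for s, e, b in [("a", 1e-30, 100), ("b", 1e-30, 150), ("c", 1e-10, 90)]
        ]
        best = {classify_hits(p, 1e-5).hit.subject_id
                for p in ([hits[0], hits[1], hits[2]], [hits[2], hits[1], hits[0]],
                          [hits[1], hits[0], hits[2]])}
        assert best == {"b"}  # same evalue, higher bitscore wins


class TestExtrapolateRrna:
    def test_plus_strand_arithmetic(self):
        hit = _hit(qstart=201, qend=700, sstart=101, send=600, subject_len=1500)
        feat = extrapolate_rrna(hit, query_len=5000)
        assert (feat.start, feat.end, feat.strand) == (101, 1600, "+")
        assert not feat.partial5 and not feat.partial3

    def test_clamped_with_partial_flag(self):
        hit = _hit(qstart=201, qend=700, sstart=101, send=600, subject_len=1500)
        feat = extrapolate_rrna(hit, query_len=1000)
        assert (feat.start, feat.end) == (101, 1000)
        assert feat.partial3 and not feat.partial5

    def test_full_reference_alignment_identity(self):
        hit = _hit(qstart=301, qend=1800, sstart=1, send=1500, subject_len=1500)
        feat = extrapolate_rrna(hit, query_len=5000)
        assert (feat.start, feat.end) == (301, 1800)

    def test_length_equals_subject_len_when_unclamped(self):
        hit = _hit(qstart=900, qend=1100, sstart=400, send=600, subject_len=1500)
        feat = extrapolate_rrna(hit, query_len=10000)
        assert feat.length == 1500

    def test_strand_flip_mirror(self):
        qlen, slen = 5000, 1500
        plus = _hit(qstart=201, qend=700, sstart=101, send=600, subject_len=slen)
        fplus = extrapolate_rrna(plus, qlen)
        # the same alignment seen on the reverse strand of the query
        minus = _hit(
            qstart=qlen - 700 + 1,
            qend=qlen - 201 + 1,
            sstart=600,
            send=101,
            subject_len=slen,
        )
        fminus = extrapolate_rrna(minus, qlen)
        assert fminus.strand == "-"
        assert (fminus.start, fminus.end) == (qlen - fplus.end + 1, qlen - fplus.start + 1)

    def test_requires_subject_len(self):
        with pytest.raises(ValueError, match="subject length"):
            extrapolate_rrna(_hit(subject_len=None), 1000)


class TestNaiveSearch:
    DB = [
        SeqRecord(id="p1", sequence="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKAL"),
        SeqRecord(id="p2", sequence="MSEALKILNNIRTLRAQARECTLETLEEMLEKLEVVVNERREEESAAAAEVEERTRKL"),
        SeqRecord(id="p3", sequence="MGHHHHHHSSGLVPRGSHMASMTGGQQMGRGSEF"),
    ]

    def test_self_hit_is_top_full_length_identity(self):
        hits = naive_search([self.DB[0]], self.DB)
        assert hits[0].subject_id == "p1"
        assert hits[0].pct_identity == 100.0
        assert hits[0].aln_length == len(self.DB[0].sequence)

    def test_no_shared_kmer_no_hits(self):
        query = SeqRecord(id="q", sequence="WWWWWWWWWWCCCCCCCCCC")
        assert naive_search([query], self.DB) == []

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            naive_search([self.DB[0]], [])

    def test_karlin_altschul_formula(self):
        # one exact worked alignment: self-hit raw score = sum of BLOSUM62
        # diagonal entries; check bitscore and e-value against closed form
        from Bio.Align import substitution_matrices

        bl = substitution_matrices.load("BLOSUM62")
        query = self.DB[1]
        raw = sum(bl[a, a] for a in query.sequence)
        lam, K = 0.267, 0.041
        bits = (lam * raw - log(K)) / log(2)
        m = len(query.sequence)
        n = sum(len(r.sequence) for r in self.DB)
        expected_e = m * n * 2.0 ** (-bits)
        hit = naive_search([query], self.DB)[0]
        assert hit.bitscore == pytest.approx(bits, abs=0.05)
        assert hit.evalue == pytest.approx(expected_e, rel=0.05)

    def test_deterministic(self):
        a = naive_search(self.DB, self.DB)
        b = naive_search(self.DB, self.DB)
        assert [(h.query_id, h.subject_id, h.evalue) for h in a] == [
            (h.query_id, h.subject_id, h.evalue) for h in b
        ]

    def test_self_hit_rank_one_for_every_db_entry(self, protein_db):
        for entry in protein_db:
            hits = naive_search([entry], protein_db)
            assert hits[0].subject_id == entry.id

    def test_engine_call_counting(self, protein_db):
        engine = NaiveEngine(protein_db)
        engine.search([protein_db[0]])
        engine.search([protein_db[1]])
        assert engine.call_count == 2
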