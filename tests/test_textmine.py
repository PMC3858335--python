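import pytest
from hypothesis import given, strategies as st

from cypscope import textmine_relations as tm
from cypscope.textmine_relations import (
    Document,
    EntityClass,
    EntityMention,
    RelationCandidate,
    ScoringParams,
    ValidationRecord,
    ValidationState,
)


def candidate(d_ce, d_fc, negated=False, doc_id="d1"):
    return RelationCandidate(doc_id, None, None, None, None, d_ce=d_ce, d_fc=d_fc, negated=negated)


# ---------------------------------------------------------------------------
# build_query


class TestBuildQuery:
    def test_published_template(self):
        assert tm.build_query("2C19", ["population"], ["effect"]) == (
            "(Abstract: CYP2C19* OR Title: CYP2C19*)"
            " AND (Abstract: population OR Title: population)"
            " AND (Abstract: effect OR Title: effect)"
            " AND (Abstract: frequenc* OR Title: frequenc*)"
        )

    def test_empty_synonym_list_rejected(self):
        with pytest.raises(ValueError, match="empty synonym list"):
            tm.build_query("2C19", [], [])

    def test_or_expansion_of_synonyms(self):
        # string-construction oracle: clauses expand pairwise in input order
        q = tm.build_query("2D6", ["population", "cohort"], ["effect"])
        assert "(Abstract: population OR Title: population OR Abstract: cohort OR Title: cohort)" in q

    def test_malformed_cyp_named_in_error(self):
        with pytest.raises(ValueError, match="2XX!"):
            tm.build_query("2XX!", ["population"], ["effect"])


# ---------------------------------------------------------------------------
# tokenize


class TestTokenize:
    def test_star_allele_is_one_token(self):
        toks = tm.tokenize("CYP2D6*4 is frequent.")
        assert [t.text for t in toks] == ["CYP2D6*4", "is", "frequent", "."]
        assert all(t.sentence_index == 0 for t in toks)

    def test_empty_text(self):
        assert tm.tokenize("") == []

    def test_sentence_indices(self):
        toks = tm.tokenize("A. B.")
        assert sorted({t.sentence_index for t in toks}) == [0, 1]
        assert [t.sentence_index for t in toks] == sorted(t.sentence_index for t in toks)

    def test_percentage_and_rsid_are_single_tokens(self):
        texts = [t.text for t in tm.tokenize("rs1065852 occurred at 81.3% overall.")]
        assert "rs1065852" in texts
        assert "81.3%" in texts

    def test_lexicon_surfaces_never_split(self, lexicon):
        # single-word lexicon surfaces must survive tokenization intact
        for entry in lexicon.entries:
            if " " in entry.surface_form:
                continue
            toks = tm.tokenize(f"prefix {entry.surface_form} suffix.")
            assert entry.surface_form in [t.text for t in toks]


# ---------------------------------------------------------------------------
# detect_mentions


class TestDetectMentions:
    def test_hand_annotated_sentence(self, lexicon):
        toks = tm.tokenize("In Caucasians CYP2C19*2 occurred at 16.0%.")
        mentions = tm.detect_mentions(toks, lexicon)
        by_class = {m.entity_class: m for m in mentions}
        assert by_class[EntityClass.ETHNICITY].canonical_id == "caucasian"
        assert by_class[EntityClass.ETHNICITY].token_start == 1
        assert by_class[EntityClass.CYP].canonical_id == "2C19"
        assert by_class[EntityClass.CYP].token_start == 2
        assert by_class[EntityClass.FREQUENCY].value == 16.0
        assert by_class[EntityClass.FREQUENCY].token_start == 5

    def test_empty_tokens(self, lexicon):
        assert tm.detect_mentions([], lexicon) == []

    def test_out_of_range_percentage_discarded(self, lexicon):
        toks = tm.tokenize("150% of samples")
        mentions = tm.detect_mentions(toks, lexicon)
        assert not [m for m in mentions if m.entity_class is EntityClass.FREQUENCY]

    def test_spaced_cyp_and_percent_word(self, lexicon):
        toks = tm.tokenize("CYP 2D6 reached 12 percent.")
        mentions = tm.detect_mentions(toks, lexicon)
        cyp = next(m for m in mentions if m.entity_class is EntityClass.CYP)
        freq = next(m for m in mentions if m.entity_class is EntityClass.FREQUENCY)
        assert cyp.canonical_id == "2D6"
        assert freq.value == 12.0

    def test_sorted_by_token_start(self, lexicon):
        toks = tm.tokenize("Caucasians and Asians carry CYP2B6 at 5.0%.")
        starts = [m.token_start for m in tm.detect_mentions(toks, lexicon)]
        assert starts == sorted(starts)

    def test_multiword_lexicon_longest_match(self):
        lex = tm.Lexicon(
            [
                tm.LexiconEntry(EntityClass.ETHNICITY, "african", "african"),
                tm.LexiconEntry(EntityClass.ETHNICITY, "african american", "african_american"),
            ]
        )
        toks = tm.tokenize("african american subjects")
        mentions = tm.detect_mentions(toks, lex)
        assert [m.canonical_id for m in mentions] == ["african_american"]


# ---------------------------------------------------------------------------
# score_relation


class TestScoreRelation:
    def test_threshold_boundary_scores_100(self):
        assert tm.score_relation(candidate(7, 6)) == 100.0

    def test_minimum_distances_score_100(self):
        assert tm.score_relation(candidate(0, 0)) == 100.0

    def test_linear_decay(self):
        # brute-force evaluation of the decay formula:
        # 100 - 10 * max(0, 9-7) - 10 * max(0, 6-6) = 80
        assert tm.score_relation(candidate(9, 6)) == 80.0

    def test_negation_halves_score(self):
        assert tm.score_relation(candidate(3, 3, negated=True)) == 50.0

    def test_floor_at_zero(self):
        assert tm.score_relation(candidate(100, 100)) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            candidate(-1, 0)

    @given(
        d_ce=st.integers(0, 40),
        d_fc=st.integers(0, 40),
        negated=st.booleans(),
        weight=st.floats(0.1, 50, allow_nan=False),
    )
    def test_score_in_range(self, d_ce, d_fc, negated, weight):
        params = ScoringParams(decay_weight=weight)
        score = tm.score_relation(candidate(d_ce, d_fc, negated), params)
        assert 0.0 <= score <= 100.0

    @given(d_ce=st.integers(0, 40), d_fc=st.integers(0, 40), negated=st.booleans())
    def test_monotone_nonincreasing_in_each_distance(self, d_ce, d_fc, negated):
        base = tm.score_relation(candidate(d_ce, d_fc, negated))
        assert tm.score_relation(candidate(d_ce + 1, d_fc, negated)) <= base
        assert tm.score_relation(candidate(d_ce, d_fc + 1, negated)) <= base


# ---------------------------------------------------------------------------
# extract_relations


class TestExtractRelations:
    def test_single_in_window_triple(self, lexicon):
        doc = Document("1", "", "In Caucasians CYP2C19 occurred at 16.0%.")
        cands = tm.extract_relations(doc, lexicon, ScoringParams(min_score=100.0))
        assert len(cands) == 1
        assert cands[0].score == 100.0
        assert cands[0].cyp.canonical_id == "2C19"
        assert cands[0].frequency.value == 16.0

    def test_cyp_only_yields_nothing(self, lexicon):
        doc = Document("1", "", "CYP2D6 metabolizes many drugs.")
        assert tm.extract_relations(doc, lexicon) == []

    def test_duplicate_triples_collapse_in_dedup(self, lexicon):
        text = "In Caucasians CYP2C19 occurred at 16.0%. In Caucasians CYP2C19 occurred at 16.0%."
        doc = Document("1", "", text)
        cands = tm.extract_relations(doc, lexicon, ScoringParams(min_score=100.0))
        assert len(cands) == 2
        assert len(tm.deduplicate(cands)) == 1

    def test_cross_sentence_disabled_by_default(self, lexicon):
        doc = Document("1", "", "CYP2C19 was studied in Caucasians. It reached 16.0%.")
        assert tm.extract_relations(doc, lexicon, ScoringParams(min_score=1.0)) == []

    def test_cross_sentence_capped_at_90(self, lexicon):
        doc = Document("1", "", "CYP2C19 was studied in Caucasians. It reached 16.0%.")
        params = ScoringParams(min_score=1.0, cross_sentence=True)
        cands = tm.extract_relations(doc, lexicon, params)
        assert cands and all(c.score <= 90.0 for c in cands)

    def test_negation_between_closest_pair(self, lexicon):
        doc = Document("1", "", "10.0% assay CYP2D6 not Caucasians today.")
        cands = tm.extract_relations(doc, lexicon, ScoringParams(min_score=1.0))
        assert len(cands) == 1
        assert cands[0].negated
        assert cands[0].score == 50.0

    def test_effect_attachment(self, lexicon):
        doc = Document("1", "", "In Caucasians CYP2C19 showed decreased activity at 16.0%.")
        cands = tm.extract_relations(doc, lexicon, ScoringParams(min_score=100.0))
        assert cands[0].effect is not None
        assert cands[0].effect.canonical_id == "decrease"

    def test_sorted_by_descending_score(self, lexicon):
        text = (
            "In Caucasians CYP2C19 occurred at 16.0%. "
            "Asians a b c d e f g h i j CYP2D6 k l m n o p q r reached 5.0% overall."
        )
        doc = Document("1", "", text)
        scores = [c.score for c in tm.extract_relations(doc, lexicon, ScoringParams(min_score=0.0))]
        assert scores == sorted(scores, reverse=True)


# ---------------------------------------------------------------------------
# deduplicate


class TestDeduplicate:
    def test_keeps_highest_score(self):
        a, b = candidate(7, 6), candidate(9, 6)
        a.score, b.score = 100.0, 80.0
        out = tm.deduplicate([b, a])
        assert len(out) == 1 and out[0].score == 100.0

    def test_empty(self):
        assert tm.deduplicate([]) == []

    def test_unique_list_unchanged(self):
        a, b = candidate(1, 1, doc_id="d1"), candidate(1, 1, doc_id="d2")
        assert tm.deduplicate([a, b]) == [a, b]

    @given(st.lists(st.tuples(st.sampled_from(["d1", "d2"]), st.integers(0, 5), st.floats(0, 100))))
    def test_idempotent(self, rows):
        cands = []
        for doc_id, d, score in rows:
            c = candidate(d, d, doc_id=doc_id)
            c.score = score
            cands.append(c)
        once = tm.deduplicate(cands)
        assert tm.deduplicate(once) == once


# ---------------------------------------------------------------------------
# validation records and export


def _full_candidate(doc_id="d1", state=ValidationState.UNREVIEWED):
    cyp = EntityMention(EntityClass.CYP, "2C19", 2, 0, "CYP2C19")
    eth = EntityMention(EntityClass.ETHNICITY, "caucasian", 1, 0, "Caucasians")
    freq = EntityMention(EntityClass.FREQUENCY, "16.0", 5, 0, "16.0%", 16.0)
    cand = RelationCandidate.from_mentions(doc_id, cyp, eth, freq)
    cand.score = 100.0
    return ValidationRecord(cand, state=state)


class TestValidationRecords:
    def test_legal_transitions(self):
        r = _full_candidate()
        r.resolve(ValidationState.NOT_SURE, reviewer="s1")
        r.resolve(ValidationState.TRUE, reviewer="s2")
        assert r.state is ValidationState.TRUE
        assert r.reviewer == "s2"

    def test_illegal_transition(self):
        r = _full_candidate(state=ValidationState.TRUE)
        with pytest.raises(ValueError, match="illegal state transition"):
            r.resolve(ValidationState.FALSE)

    def test_export_roundtrip(self, tmp_path):
        records = [_full_candidate("d1"), _full_candidate("d2")]
        records[0].resolve(ValidationState.TRUE, reviewer="s1", comment="ok")
        path = tmp_path / "records.tsv"
        tm.export_records(records, path)
        back = tm.read_records(path)
        assert [r.export_tuple() for r in back] == [r.export_tuple() for r in records]

    def test_single_true_record_row_count(self, tmp_path):
        r = _full_candidate()
        r.resolve(ValidationState.TRUE)
        path = tmp_path / "one.tsv"
        tm.export_records([r], path)
        assert len(path.read_text().splitlines()) == 2  # header + 1 row

    def test_strict_flag_rejects_unresolved(self, tmp_path):
        r = _full_candidate()
        r.resolve(ValidationState.NOT_SURE)
        with pytest.raises(ValueError, match="unresolved"):
            tm.export_records([r], tmp_path / "x.tsv", allow_unresolved=False)


class TestCorpusIO:
    def test_tsv_corpus(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        path.write_text("doc_id\ttitle\tabstract\n1\tT\tSome text.\n", encoding="utf-8")
        docs = tm.read_corpus(path)
        assert docs == [Document("1", "T", "Some text.")]

    def test_txt_directory(self, tmp_path):
        (tmp_path / "123.txt").write_text("An abstract.", encoding="utf-8")
        docs = tm.read_corpus(tmp_path)
        assert docs[0].doc_id == "123"

    def test_duplicate_doc_ids_rejected(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        path.write_text("doc_id\ttitle\tabstract\n1\tT\ta\n1\tT\tb\n", encoding="utf-8")
        with pytest.raises(ValueError, match="duplicate"):
            tm.read_corpus(path)
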