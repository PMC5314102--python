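"""Triage view models (heatmap, distribution matrix, encoded abstract) and
the three-stage session state machine."""

import io
import random

import numpy as np
import pytest

from ontotriage import (
    SessionError,
    Stage,
    TriageSession,
    build_heatmap,
    encode_abstract,
    pubmed_url,
    search,
    term_distribution,
)
from ontotriage.index import INDEX_FIELDS


@pytest.fixture
def session(five_doc_index):
    hits = search(five_doc_index, ["progressive"])
    return TriageSession(
        query_words=["progressive", "external", "ophthalmoplegia"],
        candidates=[h.pmid for h in hits],
    )


class TestHeatmap:
    def test_shape_matches_hits_and_words(self, five_doc_index):
        hits = search(five_doc_index, ["progressive"])
        words = ["progressive", "external", "ophthalmoplegia"]
        m = build_heatmap(five_doc_index, hits, words)
        assert m.counts.shape == (len(hits), 3)
        assert m.pmids == [h.pmid for h in hits]
        assert m.color_indices == [0, 1, 2]

    def test_conjunctive_words_present_in_every_row(self, five_doc_index):
        words = ["progressive", "ophthalmoplegia"]
        hits = search(five_doc_index, words)
        m = build_heatmap(five_doc_index, hits, words)
        assert (m.counts >= 1).all()

    def test_saturation_equals_naive_recount(self, five_doc_index, five_doc_citations):
        words = ["progressive", "external", "renin"]
        hits = search(five_doc_index, ["progressive"])
        m = build_heatmap(five_doc_index, hits, words)
        by_pmid = {c.pmid: c for c in five_doc_citations}
        naive = np.zeros_like(m.counts)
        for i, pmid in enumerate(m.pmids):
            c = by_pmid[pmid]
            text = " ".join(
                [c.title, c.journal] + list(c.mesh_terms) + [c.abstract]
            ).lower()
            import re

            toks = re.findall(r"[0-9a-z]+", text)
            for j, w in enumerate(words):
                naive[i, j] = toks.count(w)
        assert (m.counts == naive).all()
        col_max = naive.max(axis=0)
        for j in range(len(words)):
            for i in range(len(m.pmids)):
                want = naive[i, j] / col_max[j] if col_max[j] else 0.0
                assert m.saturation[i, j] == pytest.approx(want)

    def test_white_cell_iff_zero_count(self, five_doc_index):
        hits = search(five_doc_index, ["progressive"])
        m = build_heatmap(five_doc_index, hits, ["progressive", "renin"])
        assert ((m.saturation == 0) == (m.counts == 0)).all()

    def test_empty_hits_valid(self, five_doc_index):
        m = build_heatmap(five_doc_index, [], ["renin"])
        assert m.counts.shape == (0, 1)


class TestTermDistribution:
    def test_word_only_in_journal(self, five_doc_citations):
        # "hypertension" occurs in journal, title and mesh of pmid 11;
        # "reports" occurs only in the journal of pmid 12
        dist = term_distribution(five_doc_citations[1], ["reports"])
        assert dist.counts["reports"] == {
            "title": 0,
            "journal": 1,
            "mesh": 0,
            "abstract": 0,
        }

    def test_absent_word_all_zeros(self, five_doc_citations):
        dist = term_distribution(five_doc_citations[0], ["fibrosis"])
        assert all(v == 0 for v in dist.counts["fibrosis"].values())

    def test_field_sums_reconcile_with_heatmap(self, five_doc_index, five_doc_citations):
        words = ["progressive", "renin", "muscles"]
        hits = search(five_doc_index, ["progressive"])
        m = build_heatmap(five_doc_index, hits, words)
        by_pmid = {c.pmid: c for c in five_doc_citations}
        for i, pmid in enumerate(m.pmids):
            dist = term_distribution(by_pmid[pmid], words)
            for j, w in enumerate(words):
                assert sum(dist.counts[w].values()) == m.counts[i, j]

    def test_mesh_counts_token_occurrences_across_headings(self, five_doc_citations):
        dist = term_distribution(five_doc_citations[4], ["muscles", "oculomotor"])
        assert dist.counts["oculomotor"]["mesh"] == 1
        assert dist.counts["muscles"]["mesh"] == 1
        assert dist.counts["muscles"]["title"] == 1


class TestEncodeAbstract:
    def test_repeated_word_yields_multiple_spans(self, five_doc_citations):
        spans = encode_abstract(five_doc_citations[0], ["renin"])
        assert len(spans) == 2  # "Renin and renin receptor ..."

    def test_span_text_equals_query_word(self, five_doc_citations):
        words = ["renin", "pressure", "arterial"]
        c = five_doc_citations[0]
        for word_index, start, end in encode_abstract(c, words):
            assert c.abstract[start:end].lower() == words[word_index]

    def test_spans_sorted_and_non_overlapping(self, five_doc_citations):
        spans = encode_abstract(five_doc_citations[2], ["progressive", "fibrosis", "ophthalmoplegia"])
        starts = [s for _, s, _ in spans]
        assert starts == sorted(starts)
        for (_, s1, e1), (_, s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_span_count_reconciles_with_distribution(self, five_doc_citations):
        words = ["renin", "levels", "pressure"]
        for c in five_doc_citations:
            dist = term_distribution(c, words)
            spans = encode_abstract(c, words)
            for j, w in enumerate(words):
                n_spans = sum(1 for wi, _, _ in spans if wi == j)
                assert n_spans == dist.counts[w]["abstract"]

    def test_empty_abstract(self, five_doc_citations):
        assert encode_abstract(five_doc_citations[3], ["pressure"]) == []


class TestPubmedUrl:
    def test_default_template(self):
        assert "12345" in pubmed_url(12345)

    def test_template_override(self):
        assert pubmed_url(7, "x/{pmid}") == "x/7"

    def test_injective_over_pmid_set(self, five_doc_citations):
        urls = [pubmed_url(c.pmid) for c in five_doc_citations]
        assert len(set(urls)) == len(urls)

    @pytest.mark.parametrize("bad", [0, -5])
    def test_non_positive_pmid_rejected(self, bad):
        with pytest.raises(ValueError):
            pubmed_url(bad)

    def test_template_without_placeholder_rejected(self):
        with pytest.raises(ValueError):
            pubmed_url(1, "no-placeholder")


class TestDwell:
    def test_threshold_boundary(self, session):
        pmid = session.candidates[0]
        session.record_dwell(pmid, 4.99)
        assert pmid not in session.visited
        session.record_dwell(pmid, 0.01)
        assert pmid in session.visited

    def test_zero_dwell_no_change(self, session):
        pmid = session.candidates[0]
        session.record_dwell(pmid, 0.0)
        assert session.visited == set()

    def test_probe_smallest_marking_duration_is_threshold(self, five_doc_index):
        """Fresh sessions probed at 0.5 s steps mark first at the threshold."""
        hits = search(five_doc_index, ["progressive"])
        marked_at = []
        for tenths in range(5, 105, 5):
            s = TriageSession(query_words=["progressive"], candidates=[h.pmid for h in hits])
            s.record_dwell(s.candidates[0], tenths / 10.0)
            if s.candidates[0] in s.visited:
                marked_at.append(tenths / 10.0)
        assert min(marked_at) == 5.0

    def test_unknown_pmid_errors(self, session):
        with pytest.raises(SessionError):
            session.record_dwell(999999, 1.0)

    def test_visited_monotone_nondecreasing(self, session):
        rng = random.Random(0)
        seen = set()
        for _ in range(200):
            pmid = rng.choice(session.candidates)
            session.record_dwell(pmid, rng.random() * 2)
            assert seen <= session.visited
            seen = set(session.visited)


class TestStateMachine:
    def test_select_idempotent(self, session):
        pmid = session.candidates[0]
        session.select(pmid)
        session.select(pmid)
        assert session.selected_pile == [pmid]

    def test_select_preserves_order(self, session):
        for pmid in session.candidates[:3]:
            session.select(pmid)
        assert session.selected_pile == session.candidates[:3]

    def test_advance_requires_pile_then_reading(self, session):
        with pytest.raises(SessionError):
            session.advance()
        session.select(session.candidates[0])
        session.advance()
        assert session.stage == Stage.INDIVIDUAL_DOCUMENT
        with pytest.raises(SessionError):
            session.advance()
        session.read(session.selected_pile[0])
        session.advance()
        assert session.stage == Stage.FURTHER_READING

    def test_reject_at_stage2_removes_and_clears_reading(self, session):
        a, b = session.candidates[:2]
        session.select(a)
        session.select(b)
        session.advance()
        session.read(a)
        session.reject(a)
        assert session.selected_pile == [b]
        assert session.reading is None

    def test_read_requires_pile_membership(self, session):
        session.select(session.candidates[0])
        with pytest.raises(SessionError):
            session.read(session.candidates[1])

    def test_cursor_clamps_at_ends(self, session):
        for _ in range(len(session.candidates) + 5):
            session.navigate("next")
        assert session.cursor == len(session.candidates) - 1
        for _ in range(len(session.candidates) + 5):
            session.navigate("prev")
        assert session.cursor == 0

    def test_retreat_preserves_state(self, session):
        a = session.candidates[0]
        session.select(a)
        session.record_dwell(a, 6.0)
        session.advance()
        session.read(a)
        session.retreat()
        assert session.stage == Stage.MULTIPLE_DOCUMENT
        assert session.selected_pile == [a]
        assert session.visited == {a}
        assert session.reading == a

    def test_retreat_to_named_earlier_stage(self, session):
        session.select(session.candidates[0])
        session.advance()
        session.read(session.selected_pile[0])
        session.advance()
        session.retreat("multiple_document")
        assert session.stage == Stage.MULTIPLE_DOCUMENT
        with pytest.raises(SessionError):
            session.retreat()

    def test_roundtrip_serialization(self, session):
        session.select(session.candidates[0])
        session.record_dwell(session.candidates[0], 7.5)
        session.advance()
        text = session.to_json()
        again = TriageSession.from_json(text)
        assert again.to_json() == text
        buf = io.StringIO()
        session.save(buf)
        buf.seek(0)
        assert TriageSession.load(buf).to_json() == text
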