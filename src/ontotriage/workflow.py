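"""Scripted replay of the 7-step search-and-triage workflow.

The interactive workflow has two phases: vocabulary building (type a query,
get ontology term suggestions; pick phenotypes and inspect the
sensitivity-encoded word-combination selectors) and triaging (scan the query
result heatmap, inspect term distribution matrices, build a selected pile,
read term-encoded abstracts, and finally read one document in depth). This
module replays a recorded event script against the indices headlessly and
deterministically: the same script always yields byte-identical payloads.

Event objects are mappings with an ``op`` key::

    {"op": "suggest", "query": "liver", "limit": 10}
    {"op": "select-phenotype", "term_id": "HP:...", "name": "..."}
    {"op": "expand"}
    {"op": "select-combo", "words": ["progressive", "opthalmoplegia"]}
    {"op": "heatmap"} | {"op": "distmatrix", "pmid": N} | {"op": "abstract", "pmid": N}
    {"op": "navigate", "direction": "next"} | {"op": "dwell", "pmid": N, "seconds": 3}
    {"op": "select", "pmid": N} | {"op": "reject", "pmid": N}
    {"op": "advance"} | {"op": "read", "pmid": N} | {"op": "retreat"}

Each event emits one JSON-serializable payload; an event the state machine
forbids raises :class:`WorkflowError` naming the violated precondition.
"""

from __future__ import annotations

import json
import logging
import time
from typing import Any, Iterable

from .config import Config
from .expansion import PhenotypeSelection, expansion_table
from .index import CorpusIndex, search
from .ontology import SuggesterIndex, suggest
from .triage import (
    Stage,
    TriageSession,
    build_heatmap,
    encode_abstract,
    pubmed_url,
    term_distribution,
)

logger = logging.getLogger(__name__)


class WorkflowError(ValueError):
    """An event script step that the session state machine forbids."""


def _heatmap_payload(index: CorpusIndex, session: TriageSession) -> dict:
    rows = (
        session.candidates
        if session.stage == Stage.MULTIPLE_DOCUMENT
        else session.selected_pile
    )
    matrix = build_heatmap(index, rows, session.query_words)
    return {
        "pmids": matrix.pmids,
        "words": matrix.words,
        "color_indices": matrix.color_indices,
        "counts": matrix.counts.tolist(),
        "saturation": matrix.saturation.tolist(),
        "visited": sorted(session.visited),
    }


class WorkflowState:
    """Mutable state threaded through an event script replay."""

    def __init__(
        self,
        corpus_index: CorpusIndex,
        suggester: SuggesterIndex | None,
        config: Config | None = None,
    ) -> None:
        self.index = corpus_index
        self.suggester = suggester
        self.config = config or Config()
        self.phenotypes: list[tuple[str, str]] = []
        self.session: TriageSession | None = None

    # each handler returns the payload for its event
    def handle(self, event: dict[str, Any]) -> dict:
        op = event.get("op")
        handler = getattr(self, "_op_" + str(op).replace("-", "_"), None)
        if handler is None:
            raise WorkflowError(f"unknown op {op!r}")
        return handler(event)

    def _require_session(self) -> TriageSession:
        if self.session is None:
            raise WorkflowError("no active triage session: select a combo first")
        return self.session

    def _op_suggest(self, ev: dict) -> dict:
        if self.suggester is None:
            raise WorkflowError("no ontology index loaded")
        results = suggest(
            self.suggester,
            ev["query"],
            limit=ev.get("limit", self.config.suggestion_limit),
            field_weights=self.config.field_weights,
            url_template=self.config.term_url_template,
        )
        return {
            "op": "suggest",
            "query": ev["query"],
            "suggestions": [
                {
                    "term_id": s.term_id,
                    "name": s.name,
                    "matched_fields": sorted(s.matched_fields),
                    "score": s.score,
                    "detail_url": s.detail_url,
                }
                for s in results
            ],
        }

    def _op_select_phenotype(self, ev: dict) -> dict:
        pair = (ev["term_id"], ev["name"])
        if pair not in self.phenotypes:
            self.phenotypes.append(pair)
        return {"op": "select-phenotype", "phenotypes": list(self.phenotypes)}

    def _op_expand(self, ev: dict) -> dict:
        if not self.phenotypes:
            raise WorkflowError("no phenotypes selected")
        selection = PhenotypeSelection.from_phenotypes(
            self.phenotypes, self.config.stopwords
        )
        rows = expansion_table(
            self.index,
            selection,
            self.config.stopwords,
            self.config.combination_word_limit,
        )
        return {
            "op": "expand",
            "rows": [
                {
                    "term_id": r.term_id,
                    "combo": list(r.combo),
                    "count": r.count,
                    "additional": r.additional,
                    "bar_fraction": r.bar_fraction,
                }
                for r in rows
            ],
        }

    def _op_select_combo(self, ev: dict) -> dict:
        if not self.phenotypes:
            raise WorkflowError("no phenotypes selected")
        words = list(ev["words"])
        if not words:
            raise WorkflowError("empty combination")
        hits = search(self.index, words, conjunctive=True, cap=self.config.heatmap_cap)
        pooled = PhenotypeSelection.from_phenotypes(
            self.phenotypes, self.config.stopwords
        ).words
        self.session = TriageSession(
            query_words=pooled,
            candidates=[h.pmid for h in hits],
            dwell_threshold_s=self.config.dwell_threshold_s,
        )
        return {
            "op": "select-combo",
            "combo": words,
            "n_candidates": len(hits),
            "query_words": pooled,
        }

    def _op_heatmap(self, ev: dict) -> dict:
        session = self._require_session()
        payload = _heatmap_payload(self.index, session)
        payload["op"] = "heatmap"
        payload["stage"] = session.stage.value
        return payload

    def _op_distmatrix(self, ev: dict) -> dict:
        session = self._require_session()
        pmid = ev["pmid"]
        if pmid not in self.index.citations:
            raise WorkflowError(f"unknown pmid {pmid}")
        dist = term_distribution(self.index.citations[pmid], session.query_words)
        return {
            "op": "distmatrix",
            "pmid": pmid,
            "words": dist.words,
            "color_indices": dist.color_indices,
            "counts": dist.counts,
            "title": dist.title,
            "journal": dist.journal,
            "year": dist.year,
            "mesh_terms": dist.mesh_terms,
        }

    def _op_abstract(self, ev: dict) -> dict:
        session = self._require_session()
        pmid = ev["pmid"]
        if pmid not in self.index.citations:
            raise WorkflowError(f"unknown pmid {pmid}")
        citation = self.index.citations[pmid]
        spans = encode_abstract(citation, session.query_words)
        return {
            "op": "abstract",
            "pmid": pmid,
            "abstract": citation.abstract,
            "spans": [list(s) for s in spans],
        }

    def _op_navigate(self, ev: dict) -> dict:
        session = self._require_session()
        session.navigate(ev["direction"])
        working = session.working_set()
        return {
            "op": "navigate",
            "cursor": session.cursor,
            "pmid": working[session.cursor] if working else None,
        }

    def _op_dwell(self, ev: dict) -> dict:
        session = self._require_session()
        session.record_dwell(ev["pmid"], ev["seconds"])
        return {
            "op": "dwell",
            "pmid": ev["pmid"],
            "visited": sorted(session.visited),
        }

    def _op_select(self, ev: dict) -> dict:
        session = self._require_session()
        session.select(ev["pmid"])
        return {"op": "select", "selected_pile": list(session.selected_pile)}

    def _op_reject(self, ev: dict) -> dict:
        session = self._require_session()
        session.reject(ev["pmid"])
        return {"op": "reject", "selected_pile": list(session.selected_pile)}

    def _op_advance(self, ev: dict) -> dict:
        session = self._require_session()
        session.advance()
        return {"op": "advance", "stage": session.stage.value}

    def _op_read(self, ev: dict) -> dict:
        session = self._require_session()
        session.read(ev["pmid"])
        return {
            "op": "read",
            "pmid": ev["pmid"],
            "pubmed_url": pubmed_url(ev["pmid"], self.config.pubmed_url_template),
        }

    def _op_retreat(self, ev: dict) -> dict:
        session = self._require_session()
        session.retreat(ev.get("to"))
        return {"op": "retreat", "stage": session.stage.value}


def run_workflow(
    corpus_index: CorpusIndex,
    events: Iterable[dict[str, Any]],
    suggester: SuggesterIndex | None = None,
    config: Config | None = None,
) -> list[dict]:
    """Replay an event script; returns one payload per event.

    Raises :class:`WorkflowError` (naming the violated precondition) on the
    first forbidden step. Session invariants are re-checked after every
    event. An empty script yields an empty payload list.
    """
    state = WorkflowState(corpus_index, suggester, config)
    payloads = []
    for i, event in enumerate(events):
        t0 = time.perf_counter()
        try:
            payload = state.handle(event)
        except (WorkflowError, ValueError) as exc:
            raise WorkflowError(f"event {i} ({event.get('op')!r}): {exc}") from exc
        if state.session is not None:
            state.session.check_invariants()
        logger.info(
            "event=%d op=%s elapsed_ms=%.2f",
            i,
            event.get("op"),
            (time.perf_counter() - t0) * 1e3,
        )
        payloads.append(payload)
    return payloads


def payloads_to_bytes(payloads: list[dict]) -> bytes:
    """Canonical byte serialization used for determinism checks."""
    return json.dumps(payloads, sort_keys=True).encode("utf-8")
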