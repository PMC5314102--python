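"""Three-stage document triage: view models and session state machine.

Triage of a search result proceeds in three successive stages:

1. *multiple document* — up to 250 ranked hits are scanned via the query
   result heatmap (documents × query words, cell saturation encoding
   within-document term frequency) with a per-document term distribution
   matrix (counts in title, journal name, MeSH terms, abstract); relevant
   documents are selected into a pile;
2. *individual document* — the selected pile is re-encoded as a heatmap and
   each document's abstract is inspected with query terms marked
   (term-encoded abstract); documents are kept or rejected;
3. *further reading* — one document is read in depth via its PubMed entry.

Users may return to any earlier stage at any time with all state preserved.
Pausing on a document for 5 seconds or more (accumulated across visits)
places a visited mark beside it.

All three views share one source of truth for word → color-index mapping:
the position of the word in the session's pooled query-word list.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from ._text import token_spans, tokenize
from .config import DEFAULT_PUBMED_URL_TEMPLATE
from .corpus import Citation
from .index import INDEX_FIELDS, CorpusIndex, DocHit

SESSION_FORMAT = "ontotriage-session"
SESSION_VERSION = 1
DEFAULT_DWELL_THRESHOLD_S = 5.0


class Stage(str, enum.Enum):
    MULTIPLE_DOCUMENT = "multiple_document"
    INDIVIDUAL_DOCUMENT = "individual_document"
    FURTHER_READING = "further_reading"


_STAGE_ORDER = [
    Stage.MULTIPLE_DOCUMENT,
    Stage.INDIVIDUAL_DOCUMENT,
    Stage.FURTHER_READING,
]


@dataclass
class HeatmapMatrix:
    """Documents × query words with per-column saturation.

    ``counts[i, j]`` is the raw occurrence count of word *j* in document *i*
    pooled over title, journal, MeSH and abstract. Saturation is
    ``count / column max`` over the displayed rows, so the densest cell of
    each non-empty column is fully saturated and a white cell (saturation 0)
    means the word does not occur. ``color_indices[j]`` is the stable color
    slot of column *j*, shared with every downstream view.
    """

    pmids: list[int]
    words: list[str]
    color_indices: list[int]
    counts: np.ndarray
    saturation: np.ndarray


@dataclass
class TermDistribution:
    """Per-word counts in the four metadata places of one document."""

    pmid: int
    words: list[str]
    color_indices: list[int]
    counts: dict[str, dict[str, int]]  # word -> field -> count
    title: str
    journal: str
    year: int | None
    mesh_terms: list[str]


def build_heatmap(
    index: CorpusIndex,
    hits: Sequence[DocHit] | Sequence[int],
    query_words: Sequence[str],
) -> HeatmapMatrix:
    """Query result heatmap over the pooled query words.

    *hits* may be ranked :class:`DocHit` objects or bare PMIDs (the selected
    pile at stage 2 is a PMID list; it is encoded the same way).
    """
    pmids = [h.pmid if isinstance(h, DocHit) else int(h) for h in hits]
    words = list(query_words)
    counts = np.zeros((len(pmids), len(words)), dtype=np.int64)
    for i, pmid in enumerate(pmids):
        for j, word in enumerate(words):
            counts[i, j] = index.pooled_count(word, pmid)
    saturation = np.zeros_like(counts, dtype=np.float64)
    if counts.size:
        col_max = counts.max(axis=0)
        nonzero = col_max > 0
        saturation[:, nonzero] = counts[:, nonzero] / col_max[nonzero]
    return HeatmapMatrix(
        pmids=pmids,
        words=words,
        color_indices=list(range(len(words))),
        counts=counts,
        saturation=saturation,
    )


def term_distribution(
    citation: Citation, query_words: Sequence[str]
) -> TermDistribution:
    """Counts of each query word in title, journal, MeSH and abstract.

    MeSH counts accumulate token occurrences across all headings. Computed
    from the citation text with the shared tokenizer, so the per-word field
    sums reconcile exactly with the pooled heatmap counts.
    """
    words = list(query_words)
    counts = {w: {fld: 0 for fld in INDEX_FIELDS} for w in words}
    wset = set(words)
    for fld, texts in citation.field_texts().items():
        for text in texts:
            for tok in tokenize(text):
                if tok in wset:
                    counts[tok][fld] += 1
    return TermDistribution(
        pmid=citation.pmid,
        words=words,
        color_indices=list(range(len(words))),
        counts=counts,
        title=citation.title,
        journal=citation.journal,
        year=citation.year,
        mesh_terms=list(citation.mesh_terms),
    )


def encode_abstract(
    citation: Citation, query_words: Sequence[str]
) -> list[tuple[int, int, int]]:
    """Character spans of query-word occurrences in the abstract.

    Returns ``(word_index, start, end)`` triples — ``word_index`` is the
    word's color slot in the session's query-word list — sorted by start
    offset. Matching is case-insensitive on token boundaries, so the
    lowercased span text equals the query word. An empty abstract yields an
    empty list.
    """
    word_index = {w: i for i, w in enumerate(query_words)}
    spans = []
    for tok, start, end in token_spans(citation.abstract):
        if tok in word_index:
            spans.append((word_index[tok], start, end))
    return spans


def pubmed_url(pmid: int, template: str = DEFAULT_PUBMED_URL_TEMPLATE) -> str:
    """Deterministic PubMed entry URL for a PMID (no network access)."""
    if not isinstance(pmid, int) or pmid <= 0:
        raise ValueError(f"pmid must be a positive integer, got {pmid!r}")
    if template.count("{pmid}") != 1:
        raise ValueError(
            "url template must contain the {pmid} placeholder exactly once"
        )
    return template.format(pmid=pmid)


class SessionError(ValueError):
    """A triage operation that would violate the session state machine."""


@dataclass
class TriageSession:
    """Staged triage state over one ranked candidate list.

    The candidate list is fixed at session start (stage 1); the selected
    pile (stage 2) is an ordered subset of it; the reading focus (stage 3)
    is a member of the pile. Dwell time accumulates per document across
    visits and a document joins the visited set exactly when its total
    reaches ``dwell_threshold_s``. Retreating to an earlier stage preserves
    all state.
    """

    query_words: list[str]
    candidates: list[int]
    cursor: int = 0
    dwell: dict[int, float] = field(default_factory=dict)
    visited: set[int] = field(default_factory=set)
    selected_pile: list[int] = field(default_factory=list)
    reading: int | None = None
    stage: Stage = Stage.MULTIPLE_DOCUMENT
    dwell_threshold_s: float = DEFAULT_DWELL_THRESHOLD_S

    # -- working set -------------------------------------------------------
    def working_set(self) -> list[int]:
        """The document list the cursor ranges over in the current stage."""
        if self.stage == Stage.MULTIPLE_DOCUMENT:
            return self.candidates
        return self.selected_pile

    # -- stage-1/2 interactions -------------------------------------------
    def record_dwell(self, pmid: int, seconds: float) -> "TriageSession":
        if pmid not in set(self.candidates):
            raise SessionError(f"pmid {pmid} is not a candidate")
        if seconds < 0:
            raise SessionError("dwell seconds must be >= 0")
        self.dwell[pmid] = self.dwell.get(pmid, 0.0) + seconds
        if self.dwell[pmid] >= self.dwell_threshold_s:
            self.visited.add(pmid)
        return self

    def navigate(self, direction: str) -> "TriageSession":
        if direction not in ("prev", "next"):
            raise SessionError(f"unknown direction {direction!r}")
        step = -1 if direction == "prev" else 1
        upper = max(len(self.working_set()) - 1, 0)
        self.cursor = min(max(self.cursor + step, 0), upper)
        return self

    def select(self, pmid: int) -> "TriageSession":
        if self.stage == Stage.MULTIPLE_DOCUMENT:
            if pmid not in set(self.candidates):
                raise SessionError(f"pmid {pmid} is not a candidate")
        elif self.stage == Stage.INDIVIDUAL_DOCUMENT:
            if pmid not in self.selected_pile:
                raise SessionError(f"pmid {pmid} is not in the selected pile")
        else:
            raise SessionError("select is not available at the reading stage")
        if pmid not in self.selected_pile:
            self.selected_pile.append(pmid)
        return self

    def reject(self, pmid: int) -> "TriageSession":
        """Discard a document from the current stage's working set.

        At stage 1 a rejected candidate is simply never selected (no
        explicit reject list); at stage 2 the document is removed from the
        selected pile and, if it was the reading focus, the focus clears.
        """
        if self.stage == Stage.MULTIPLE_DOCUMENT:
            if pmid not in set(self.candidates):
                raise SessionError(f"pmid {pmid} is not a candidate")
            return self
        if self.stage == Stage.INDIVIDUAL_DOCUMENT:
            if pmid not in self.selected_pile:
                raise SessionError(f"pmid {pmid} is not in the selected pile")
            self.selected_pile.remove(pmid)
            if self.reading == pmid:
                self.reading = None
            self.cursor = min(self.cursor, max(len(self.selected_pile) - 1, 0))
            return self
        raise SessionError("reject is not available at the reading stage")

    def read(self, pmid: int) -> "TriageSession":
        if pmid not in self.selected_pile:
            raise SessionError(f"cannot read pmid {pmid}: not in the selected pile")
        self.reading = pmid
        return self

    # -- stage transitions -------------------------------------------------
    def advance(self) -> "TriageSession":
        if self.stage == Stage.MULTIPLE_DOCUMENT:
            if not self.selected_pile:
                raise SessionError("cannot advance with an empty selected pile")
            self.stage = Stage.INDIVIDUAL_DOCUMENT
        elif self.stage == Stage.INDIVIDUAL_DOCUMENT:
            if self.reading is None:
                raise SessionError("cannot advance without a reading focus")
            self.stage = Stage.FURTHER_READING
        else:
            raise SessionError("already at the final stage")
        self.cursor = min(self.cursor, max(len(self.working_set()) - 1, 0))
        return self

    def retreat(self, to: Stage | str | None = None) -> "TriageSession":
        """Return to an earlier stage (default: one step back), keeping state."""
        target = Stage(to) if to is not None else None
        idx = _STAGE_ORDER.index(self.stage)
        if target is None:
            if idx == 0:
                raise SessionError("already at the first stage")
            target = _STAGE_ORDER[idx - 1]
        elif _STAGE_ORDER.index(target) >= idx:
            raise SessionError(f"retreat target {target.value} is not earlier")
        self.stage = target
        self.cursor = min(self.cursor, max(len(self.working_set()) - 1, 0))
        return self

    # -- integrity ---------------------------------------------------------
    def check_invariants(self) -> None:
        """Raise AssertionError if any session invariant is violated."""
        cand = set(self.candidates)
        assert len(self.candidates) == len(cand), "duplicate candidates"
        pile = set(self.selected_pile)
        assert len(self.selected_pile) == len(pile), "duplicate pile entries"
        assert pile <= cand, "selected pile not a subset of candidates"
        if self.reading is not None:
            assert self.reading in pile, "reading focus outside selected pile"
        assert set(self.dwell) <= cand, "dwell recorded for non-candidate"
        assert self.visited <= set(self.dwell), "visited without dwell"
        for pmid in self.visited:
            assert self.dwell[pmid] >= self.dwell_threshold_s
        upper = max(len(self.working_set()) - 1, 0)
        assert 0 <= self.cursor <= upper, "cursor out of range"
        assert self.stage in _STAGE_ORDER

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": SESSION_FORMAT,
            "version": SESSION_VERSION,
            "query_words": self.query_words,
            "candidates": self.candidates,
            "cursor": self.cursor,
            "dwell": {str(k): v for k, v in sorted(self.dwell.items())},
            "visited": sorted(self.visited),
            "selected_pile": self.selected_pile,
            "reading": self.reading,
            "stage": self.stage.value,
            "dwell_threshold_s": self.dwell_threshold_s,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TriageSession":
        obj = json.loads(text)
        if obj.get("format") != SESSION_FORMAT or obj.get("version") != SESSION_VERSION:
            raise ValueError("unrecognized session document")
        session = cls(
            query_words=list(obj["query_words"]),
            candidates=list(obj["candidates"]),
            cursor=obj["cursor"],
            dwell={int(k): v for k, v in obj["dwell"].items()},
            visited=set(obj["visited"]),
            selected_pile=list(obj["selected_pile"]),
            reading=obj["reading"],
            stage=Stage(obj["stage"]),
            dwell_threshold_s=obj["dwell_threshold_s"],
        )
        session.check_invariants()
        return session

    def save(self, stream: IO[str]) -> None:
        stream.write(self.to_json() + "\n")

    @classmethod
    def load(cls, stream: IO[str]) -> "TriageSession":
        return cls.from_json(stream.read())
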