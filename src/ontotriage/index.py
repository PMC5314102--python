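"""Field-aware inverted index with tf-idf weighting and cosine ranking.

Documents are ranked by the vector space model: each document is a vector
over index terms weighted by tf-idf, and a query scores against it by cosine
similarity. The weighting is the classic dampened-tf variant:

    doc weight(t, d)  = sqrt(tf(t, d)) * idf(t)
    idf(t)            = 1 + ln(N / (1 + df(t)))
    query weight(t)   = idf(t)
    score(q, d)       = <q, d> / (|q| * |d|)

where ``tf(t, d)`` pools raw counts over the four text places of a citation
(title, journal name, MeSH headings, abstract) and ``df(t)`` counts documents
containing *t* in any of them. Per-field counts are retained for the triage
views; scoring itself applies no per-field boosts.

Search is conjunctive by default — a candidate must contain every query
token — which is what the triage workflow uses; disjunctive (any-token)
matching is available for broader recall. Results are capped for display
(default 250 documents), ties broken by PMID descending (newer first).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._text import tokenize
from .corpus import Citation, read_jsonl, write_jsonl

INDEX_FIELDS = ("title", "journal", "mesh", "abstract")
INDEX_FORMAT = "ontotriage-corpus-index"
INDEX_VERSION = 1
DEFAULT_CAP = 250


@dataclass
class DocHit:
    """One ranked search result."""

    pmid: int
    score: float
    rank: int  # 1-based position in the result list


class CorpusIndex:
    """Inverted index over a citation corpus.

    Attributes
    ----------
    N : int
        Number of indexed documents.
    postings : dict
        ``token -> {pmid -> {field -> raw count}}``.
    df : dict
        ``token -> number of documents containing the token in any field``.
    doc_norms : dict
        ``pmid -> Euclidean norm of the document's tf-idf vector``.
    citations : dict
        ``pmid -> Citation`` (kept for the triage views).
    """

    def __init__(self, citations: Iterable[Citation]) -> None:
        self.citations: dict[int, Citation] = {}
        self.postings: dict[str, dict[int, dict[str, int]]] = {}
        for c in citations:
            if c.pmid in self.citations:
                raise ValueError(f"duplicate PMID in corpus: {c.pmid}")
            self.citations[c.pmid] = c
            for fld, texts in c.field_texts().items():
                for text in texts:
                    for tok in tokenize(text):
                        per_doc = self.postings.setdefault(tok, {})
                        per_field = per_doc.setdefault(c.pmid, {})
                        per_field[fld] = per_field.get(fld, 0) + 1
        self.N = len(self.citations)
        self.df = {tok: len(per_doc) for tok, per_doc in self.postings.items()}
        self.doc_norms = self._compute_norms()

    def _compute_norms(self) -> dict[int, float]:
        sq: dict[int, float] = {pmid: 0.0 for pmid in self.citations}
        for tok, per_doc in self.postings.items():
            w_idf = self.idf(tok)
            for pmid, per_field in per_doc.items():
                tf = sum(per_field.values())
                sq[pmid] += (math.sqrt(tf) * w_idf) ** 2
        return {pmid: math.sqrt(v) for pmid, v in sq.items()}

    def idf(self, token: str) -> float:
        """Smoothed inverse document frequency; defined for unseen tokens."""
        return 1.0 + math.log(self.N / (1.0 + self.df.get(token, 0)))

    def pooled_count(self, token: str, pmid: int) -> int:
        """Raw count of *token* in *pmid*, summed over the four fields."""
        return sum(self.postings.get(token, {}).get(pmid, {}).values())

    def field_count(self, token: str, pmid: int, fld: str) -> int:
        return self.postings.get(token, {}).get(pmid, {}).get(fld, 0)


def build_corpus_index(citations: Iterable[Citation]) -> CorpusIndex:
    """Build the inverted index; deterministic for a given corpus."""
    return CorpusIndex(citations)


def score(index: CorpusIndex, query_tokens: Sequence[str], pmid: int) -> float:
    """Cosine similarity between the query and one document.

    Duplicate query tokens collapse to one dimension (the query vector has a
    single idf-weighted coordinate per distinct token), so the score is
    invariant to token order and repetition. Documents containing no query
    token score 0. Unknown PMIDs raise ``KeyError``.
    """
    if pmid not in index.citations:
        raise KeyError(f"unknown pmid: {pmid}")
    if index.N == 0:
        return 0.0
    distinct = sorted(set(query_tokens))
    if not distinct:
        return 0.0
    q_weights = {t: index.idf(t) for t in distinct}
    q_norm = math.sqrt(sum(w * w for w in q_weights.values()))
    dot = 0.0
    hit = False
    for t, qw in q_weights.items():
        tf = index.pooled_count(t, pmid)
        if tf:
            hit = True
            dot += qw * (math.sqrt(tf) * index.idf(t))
    if not hit:
        return 0.0
    return dot / (index.doc_norms[pmid] * q_norm)


def candidate_pmids(
    index: CorpusIndex, query_tokens: Sequence[str], conjunctive: bool = True
) -> set[int]:
    """PMIDs containing all (conjunctive) or any (disjunctive) query token."""
    distinct = set(query_tokens)
    if not distinct:
        raise ValueError("empty query")
    sets = [set(index.postings.get(t, {})) for t in distinct]
    if conjunctive:
        out = set.intersection(*sets)
    else:
        out = set.union(*sets)
    return out


def count_matching(index: CorpusIndex, query_tokens: Sequence[str]) -> int:
    """Uncapped conjunctive match count (used by sensitivity expansion)."""
    return len(candidate_pmids(index, query_tokens, conjunctive=True))


def search(
    index: CorpusIndex,
    query_tokens: Sequence[str],
    conjunctive: bool = True,
    cap: int | None = DEFAULT_CAP,
) -> list[DocHit]:
    """Ranked search, truncated to *cap* hits (``None`` for unlimited).

    Candidates are scored by :func:`score`, sorted by score descending with
    ties broken by PMID descending, and capped for display.
    """
    cands = candidate_pmids(index, query_tokens, conjunctive)
    scored = [(score(index, query_tokens, pmid), pmid) for pmid in cands]
    scored.sort(key=lambda sp: (-sp[0], -sp[1]))
    if cap is not None:
        scored = scored[:cap]
    return [
        DocHit(pmid=pmid, score=s, rank=i + 1) for i, (s, pmid) in enumerate(scored)
    ]


def save_index(index: CorpusIndex, directory: str) -> None:
    """Persist the index to *directory* (versioned text layout).

    Layout: ``meta.json`` (format id, version, document count), ``corpus.jsonl``
    (the citations), ``postings.json`` (token -> pmid -> field counts) and
    ``stats.json`` (df and doc norms).
    """
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "meta.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {"format": INDEX_FORMAT, "version": INDEX_VERSION, "n_docs": index.N},
            fh,
        )
    with open(os.path.join(directory, "corpus.jsonl"), "w", encoding="utf-8") as fh:
        write_jsonl(
            (index.citations[p] for p in sorted(index.citations)), fh
        )
    with open(os.path.join(directory, "postings.json"), "w", encoding="utf-8") as fh:
        json.dump(index.postings, fh, sort_keys=True)
    with open(os.path.join(directory, "stats.json"), "w", encoding="utf-8") as fh:
        json.dump({"df": index.df, "doc_norms": index.doc_norms}, fh, sort_keys=True)


def load_index(directory: str) -> CorpusIndex:
    """Load an index persisted by :func:`save_index`."""
    with open(os.path.join(directory, "meta.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta.get("format") != INDEX_FORMAT or meta.get("version") != INDEX_VERSION:
        raise ValueError(f"unrecognized index format in {directory!r}: {meta}")
    with open(os.path.join(directory, "corpus.jsonl"), "r", encoding="utf-8") as fh:
        citations = read_jsonl(fh)
    index = CorpusIndex(citations)
    if index.N != meta["n_docs"]:
        raise ValueError("index corrupt: document count mismatch")
    return index
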