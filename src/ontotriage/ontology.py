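"""OBO ontology parsing and as-you-type term suggestion.

Parses OBO 1.2/1.4 flat files (HPO-style ``[Term]`` stanzas) into
:class:`OntologyTerm` records and builds a :class:`SuggesterIndex` over every
text field of every non-obsolete term — name, definition, synonyms and expert
commentary — so that a query like ``liver`` surfaces phenotypes such as
*Ascites* whose connection to the liver is stated only in their definition,
not their name.

Suggestion matching treats the last query word as a prefix (the query is
re-run on every keystroke) and earlier words as whole tokens. Ranking is by
the sum of weights of the fields matched: name > synonym > definition >
comment, ties broken by term accession ascending. The weights are
configurable; the defaults encode the intuition that a hit on the label
itself is stronger evidence of relevance than a hit buried in commentary.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from ._text import tokenize
from .config import DEFAULT_FIELD_WEIGHTS, DEFAULT_TERM_URL_TEMPLATE

FIELDS = ("name", "definition", "synonym", "comment")

_QUOTED_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')
_TERM_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*:[A-Za-z0-9_.-]+$")


class OboParseError(ValueError):
    """Malformed OBO input; the message names the offending line."""


@dataclass
class OntologyTerm:
    """One ontology entry with all indexed text fields.

    ``parents`` holds the accessions of ``is_a`` targets; whether they
    resolve is recorded on the collection, not the term.
    """

    term_id: str
    name: str
    definition: str = ""
    synonyms: list[str] = field(default_factory=list)
    comment: str = ""
    parents: list[str] = field(default_factory=list)
    obsolete: bool = False

    def field_text(self, field_name: str) -> list[str]:
        """The raw strings carried by one indexed field."""
        if field_name == "name":
            return [self.name] if self.name else []
        if field_name == "definition":
            return [self.definition] if self.definition else []
        if field_name == "synonym":
            return list(self.synonyms)
        if field_name == "comment":
            return [self.comment] if self.comment else []
        raise KeyError(field_name)


@dataclass
class OntologyCollection:
    """An ordered set of terms plus referential-integrity diagnostics."""

    terms: dict[str, OntologyTerm]
    dangling: list[tuple[str, str]] = field(default_factory=list)
    """(term_id, parent_id) pairs whose parent is absent from the collection."""

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> OntologyTerm:
        return self.terms[term_id]


def _unescape(text: str) -> str:
    return re.sub(r"\\(.)", r"\1", text)


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _quoted_value(value: str, lineno: int, tag: str) -> str:
    m = _QUOTED_RE.search(value)
    if not m:
        raise OboParseError(f"line {lineno}: {tag} value is not quoted: {value!r}")
    return _unescape(m.group(1))


def parse_obo(stream: IO[str] | Iterable[str]) -> OntologyCollection:
    """Parse an OBO flat file into an :class:`OntologyCollection`.

    ``[Term]`` stanzas are mapped to :class:`OntologyTerm`; obsolete terms are
    retained with ``obsolete=True``. Synonym scope qualifiers (EXACT, BROAD,
    ...) and trailing xref lists are stripped to the bare synonym text; the
    ``! name`` comment after an ``is_a`` target is dropped. Unknown tags and
    non-Term stanzas are ignored. A stanza without an ``id`` raises
    :class:`OboParseError` naming the line.
    """
    terms: dict[str, OntologyTerm] = {}
    cur: dict | None = None
    cur_is_term = False
    stanza_line = 0

    def flush() -> None:
        nonlocal cur
        if cur is None or not cur_is_term:
            cur = None
            return
        if "id" not in cur:
            raise OboParseError(
                f"line {stanza_line}: [Term] stanza without an id tag"
            )
        term_id = cur["id"]
        if term_id in terms:
            raise OboParseError(
                f"line {stanza_line}: duplicate term id {term_id!r}"
            )
        obsolete = cur.get("obsolete", False)
        name = cur.get("name", "")
        if not name and not obsolete:
            raise OboParseError(
                f"line {stanza_line}: non-obsolete term {term_id!r} has no name"
            )
        terms[term_id] = OntologyTerm(
            term_id=term_id,
            name=name,
            definition=cur.get("definition", ""),
            synonyms=cur.get("synonyms", []),
            comment=cur.get("comment", ""),
            parents=cur.get("parents", []),
            obsolete=obsolete,
        )
        cur = None

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("!"):
            continue
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("["):
            flush()
            cur = {}
            cur_is_term = stripped == "[Term]"
            stanza_line = lineno
            continue
        if cur is None:
            continue  # header lines (format-version etc.)
        if ":" not in stripped:
            raise OboParseError(f"line {lineno}: expected tag: value, got {stripped!r}")
        tag, _, value = stripped.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            cur["id"] = value
        elif tag == "name":
            cur["name"] = value
        elif tag == "def":
            cur["definition"] = _quoted_value(value, lineno, "def")
        elif tag == "synonym":
            cur.setdefault("synonyms", []).append(
                _quoted_value(value, lineno, "synonym")
            )
        elif tag == "comment":
            cur["comment"] = value
        elif tag == "is_a":
            cur.setdefault("parents", []).append(value.split("!")[0].strip())
        elif tag == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
        # all other tags (xref, alt_id, subset, ...) are ignored
    flush()

    dangling = [
        (t.term_id, p) for t in terms.values() for p in t.parents if p not in terms
    ]
    return OntologyCollection(terms=terms, dangling=dangling)


def write_obo(collection: OntologyCollection) -> str:
    """Serialize a collection back to canonical OBO text.

    The writer emits only the fields this package parses, so
    ``parse_obo(write_obo(parse_obo(x)))`` is the identity on those fields.
    """
    out = ["format-version: 1.2", ""]
    for term in collection:
        out.append("[Term]")
        out.append(f"id: {term.term_id}")
        if term.name:
            out.append(f"name: {term.name}")
        if term.definition:
            out.append(f'def: "{_escape(term.definition)}" []')
        for syn in term.synonyms:
            out.append(f'synonym: "{_escape(syn)}" EXACT []')
        if term.comment:
            out.append(f"comment: {term.comment}")
        for parent in term.parents:
            out.append(f"is_a: {parent}")
        if term.obsolete:
            out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out)


@dataclass
class Suggestion:
    """One ranked suggestion for a partial query."""

    term_id: str
    name: str
    matched_fields: frozenset[str]
    score: float
    detail_url: str


class SuggesterIndex:
    """Inverted index over every text field of every non-obsolete term.

    Postings map a normalized token to the set of ``(term_id, field)`` pairs
    whose raw text contains it; a sorted token list supports prefix lookup
    for the as-you-type behaviour.
    """

    def __init__(self, collection: OntologyCollection) -> None:
        self.collection = collection
        self.postings: dict[str, set[tuple[str, str]]] = {}
        for term in collection:
            if term.obsolete:
                continue
            for field_name in FIELDS:
                for text in term.field_text(field_name):
                    for tok in tokenize(text):
                        self.postings.setdefault(tok, set()).add(
                            (term.term_id, field_name)
                        )
        self._sorted_tokens = sorted(self.postings)

    def n_postings(self) -> int:
        """Total number of distinct (token, term, field) postings."""
        return sum(len(v) for v in self.postings.values())

    def tokens_with_prefix(self, prefix: str) -> list[str]:
        toks = self._sorted_tokens
        lo = bisect_left(toks, prefix)
        hi = bisect_left(toks, prefix + "\U0010ffff")
        return toks[lo:hi]


def build_suggester(collection: OntologyCollection) -> SuggesterIndex:
    """Index name, definition, synonyms and comment of each active term."""
    return SuggesterIndex(collection)


def suggest(
    index: SuggesterIndex,
    partial_query: str,
    limit: int = 25,
    field_weights: Mapping[str, float] | None = None,
    url_template: str = DEFAULT_TERM_URL_TEMPLATE,
) -> list[Suggestion]:
    """Ranked term suggestions for a partial query.

    The last query word is matched as a token prefix, earlier words as whole
    tokens; a term qualifies only if every query word matches in some field.
    Score is the sum of field weights over the matched fields, so a term hit
    in both name and definition outranks one hit in definition alone. Ties
    break by term accession ascending; output is truncated to *limit*.
    Empty or whitespace queries yield an empty list. Obsolete terms are never
    indexed, hence never suggested.
    """
    weights = dict(field_weights) if field_weights else dict(DEFAULT_FIELD_WEIGHTS)
    words = tokenize(partial_query)
    if not words:
        return []
    per_word_posts: list[set[tuple[str, str]]] = []
    for word in words[:-1]:
        per_word_posts.append(set(index.postings.get(word, ())))
    last = words[-1]
    prefix_posts: set[tuple[str, str]] = set()
    for tok in index.tokens_with_prefix(last):
        prefix_posts |= index.postings[tok]
    per_word_posts.append(prefix_posts)

    candidates: set[str] | None = None
    for posts in per_word_posts:
        ids = {term_id for term_id, _ in posts}
        candidates = ids if candidates is None else candidates & ids
    assert candidates is not None

    suggestions = []
    for term_id in candidates:
        matched = frozenset(
            f for posts in per_word_posts for tid, f in posts if tid == term_id
        )
        score = sum(weights[f] for f in matched)
        if score <= 0:
            continue
        suggestions.append(
            Suggestion(
                term_id=term_id,
                name=index.collection[term_id].name,
                matched_fields=matched,
                score=score,
                detail_url=term_detail_url(term_id, url_template),
            )
        )
    suggestions.sort(key=lambda s: (-s.score, s.term_id))
    return suggestions[:limit]


def term_detail_url(
    term_id: str, template: str = DEFAULT_TERM_URL_TEMPLATE
) -> str:
    """Deterministic detail-page URL for a term (no network access).

    *template* must contain the ``{term_id}`` placeholder exactly once.
    """
    if not _TERM_ID_RE.match(term_id or ""):
        raise ValueError(f"malformed term id: {term_id!r}")
    if template.count("{term_id}") != 1:
        raise ValueError(
            "url template must contain the {term_id} placeholder exactly once"
        )
    return template.format(term_id=term_id)
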