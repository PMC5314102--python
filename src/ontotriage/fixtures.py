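"""Deterministic synthetic ontologies and citation corpora.

Every other module is testable without downloading MEDLINE or a real
ontology: this module generates citation corpora with *exact* planted
co-occurrence structure (e.g. "exactly 10 documents contain all of
{a, b, c}") and OBO ontologies with planted cross-field matches (e.g. a
probe word present only in one term's definition), together with
ground-truth tables sufficient to verify every index statistic without
re-deriving anything from text.

Exactness is achieved with a two-stage scheme. Planted words are reserved:
they occur only in documents explicitly assigned to a planted word-set, and
a document assigned to set S receives exactly the words of S — so the number
of documents matching a conjunctive query over any planted set T is the sum
of assignments over supersets of T, solvable exactly from the requested
counts. Background words are then filled in with exact per-word document
frequencies drawn from a Zipf-like rank distribution, giving a realistic
idf spread without touching the planted counts. All randomness flows through
the single seed in the spec; the same seed yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field
from typing import Sequence

from .corpus import Citation
from .ontology import OntologyCollection, parse_obo

CORPUS_FIELDS = ("title", "journal", "mesh", "abstract")


class FixtureSpecError(ValueError):
    """Inconsistent fixture specification, detected before generation."""


@dataclass
class CorpusSpec:
    """Specification of a synthetic citation corpus.

    Attributes
    ----------
    n_docs : int
        Corpus size.
    vocabulary : list of str
        Background words (must be disjoint from planted words).
    doc_freqs : dict, optional
        Exact document frequency per background word; defaults to a
        Zipf-like schedule ``max(1, n_docs // (2 * rank))``.
    planted : list of (words, count)
        Each entry demands that *exactly* ``count`` documents contain all of
        ``words`` (conjunctively, anywhere in their four text fields).
    field_probs : dict
        Placement probability of each word occurrence into
        title/journal/mesh/abstract.
    seed : int
        Single source of randomness.
    """

    n_docs: int
    vocabulary: list[str] = dc_field(default_factory=list)
    doc_freqs: dict[str, int] | None = None
    planted: list[tuple[Sequence[str], int]] = dc_field(default_factory=list)
    field_probs: dict[str, float] = dc_field(
        default_factory=lambda: {
            "title": 0.25,
            "journal": 0.05,
            "mesh": 0.20,
            "abstract": 0.50,
        }
    )
    seed: int = 0

    def planted_sets(self) -> list[tuple[frozenset[str], int]]:
        return [(frozenset(words), count) for words, count in self.planted]


@dataclass
class OntologySpec:
    """Specification of a synthetic OBO ontology.

    ``definition_plants`` maps probe words to term positions whose
    *definition* (and only the definition) will contain the word —
    reproducing the scenario where a query matches a term through its
    description rather than its name. ``synonym_plants`` does the same for
    the synonym field.
    """

    n_terms: int
    synonym_rate: float = 0.3
    definition_plants: list[tuple[str, int]] = dc_field(default_factory=list)
    synonym_plants: list[tuple[str, int]] = dc_field(default_factory=list)
    parent_density: float = 0.5
    id_prefix: str = "SYN"
    seed: int = 0


def _solve_exact_assignments(
    planted: list[tuple[frozenset[str], int]]
) -> dict[frozenset[str], int]:
    """Documents to assign per exact word-set so conjunctive counts match.

    count(T) = sum of assignments over sets S >= T, so processing sets from
    largest to smallest, assignment(S) = requested(S) - sum over proper
    supersets already assigned. Negative assignments mean the requested
    counts are mutually inconsistent.
    """
    by_set = {}
    for words, count in planted:
        if not words:
            raise FixtureSpecError("planted word set may not be empty")
        if words in by_set:
            raise FixtureSpecError(f"duplicate planted set {sorted(words)}")
        if count < 0:
            raise FixtureSpecError("planted counts must be >= 0")
        by_set[words] = count
    assignments: dict[frozenset[str], int] = {}
    for s in sorted(by_set, key=len, reverse=True):
        superset_total = sum(
            n for t, n in assignments.items() if s < t
        )
        n = by_set[s] - superset_total
        if n < 0:
            raise FixtureSpecError(
                f"planted counts inconsistent: {sorted(s)} requests {by_set[s]} "
                f"but supersets already account for {superset_total}"
            )
        assignments[s] = n
    return assignments


def _pick_field(rng: random.Random, field_probs: dict[str, float]) -> str:
    r = rng.random()
    acc = 0.0
    for fld in CORPUS_FIELDS:
        acc += field_probs.get(fld, 0.0)
        if r < acc:
            return fld
    return "abstract"


def generate_corpus(
    spec: CorpusSpec,
) -> tuple[list[Citation], dict]:
    """Generate a corpus plus its ground-truth table.

    Returns ``(citations, truth)`` where ``truth`` has keys:

    - ``field_counts``: pmid -> word -> field -> exact count (every token of
      every document, boilerplate included);
    - ``df``: word -> document frequency;
    - ``planted_counts``: "w1 w2 ..." (sorted) -> exact conjunctive count.
    """
    planted = spec.planted_sets()
    planted_words = frozenset(w for s, _ in planted for w in s)
    overlap = planted_words & set(spec.vocabulary)
    if overlap:
        raise FixtureSpecError(
            f"background vocabulary overlaps planted words: {sorted(overlap)}"
        )
    if spec.n_docs < 0:
        raise FixtureSpecError("n_docs must be >= 0")
    if abs(sum(spec.field_probs.get(f, 0.0) for f in CORPUS_FIELDS) - 1.0) > 1e-9:
        raise FixtureSpecError("field_probs must sum to 1")
    assignments = _solve_exact_assignments(planted)
    n_planted_docs = sum(assignments.values())
    if n_planted_docs > spec.n_docs:
        raise FixtureSpecError(
            f"planted sets require {n_planted_docs} documents, spec has {spec.n_docs}"
        )

    doc_freqs = spec.doc_freqs
    if doc_freqs is None:
        doc_freqs = {
            w: max(1, spec.n_docs // (2 * (rank + 1)))
            for rank, w in enumerate(spec.vocabulary)
        }
    bad = [w for w, d in doc_freqs.items() if not 0 <= d <= spec.n_docs]
    if bad:
        raise FixtureSpecError(f"doc_freqs out of range for: {bad}")

    rng = random.Random(spec.seed)
    pmids = [100001 + i for i in range(spec.n_docs)]
    # word -> field -> count, per document
    doc_words: list[dict[str, dict[str, int]]] = [{} for _ in pmids]

    def place(doc_i: int, word: str, occurrences: int) -> None:
        per_field = doc_words[doc_i].setdefault(word, {})
        for _ in range(occurrences):
            fld = _pick_field(rng, spec.field_probs)
            per_field[fld] = per_field.get(fld, 0) + 1

    # stage 1: exact planted membership (shuffled document slots)
    slots = list(range(spec.n_docs))
    rng.shuffle(slots)
    slot_iter = iter(slots)
    for s in sorted(assignments, key=lambda t: (len(t), sorted(t)), reverse=True):
        for _ in range(assignments[s]):
            doc_i = next(slot_iter)
            for word in sorted(s):
                place(doc_i, word, 1 + rng.randrange(3))

    # stage 2: background fill with exact per-word document frequencies
    for word in spec.vocabulary:
        members = rng.sample(range(spec.n_docs), doc_freqs[word])
        for doc_i in members:
            place(doc_i, word, 1 + rng.randrange(2))

    citations: list[Citation] = []
    field_counts: dict[int, dict[str, dict[str, int]]] = {}
    for doc_i, pmid in enumerate(pmids):
        words = doc_words[doc_i]
        # every document carries a unique title token so titles are non-empty
        marker = f"doc{pmid}"
        title_words = [marker]
        journal_words: list[str] = []
        mesh_terms: list[str] = []
        abstract_words: list[str] = []
        for word in sorted(words):
            for fld, count in sorted(words[word].items()):
                if fld == "title":
                    title_words.extend([word] * count)
                elif fld == "journal":
                    journal_words.extend([word] * count)
                elif fld == "mesh":
                    mesh_terms.extend([word] * count)
                else:
                    abstract_words.extend([word] * count)
        rng.shuffle(abstract_words)
        citation = Citation(
            pmid=pmid,
            title=" ".join(title_words),
            abstract=" ".join(abstract_words),
            journal=" ".join(journal_words),
            year=1990 + rng.randrange(31),
            mesh_terms=mesh_terms,
            authors=[f"Author{doc_i} A"],
        )
        citations.append(citation)
        truth_counts = {marker: {"title": 1}}
        for word, per_field in words.items():
            truth_counts[word] = dict(per_field)
        field_counts[pmid] = truth_counts

    df = {}
    for pmid, per_word in field_counts.items():
        for word in per_word:
            df[word] = df.get(word, 0) + 1
    planted_counts = {
        " ".join(sorted(s)): count for s, count in planted
    }
    truth = {
        "field_counts": field_counts,
        "df": df,
        "planted_counts": planted_counts,
    }
    return citations, truth


_NAME_VOCAB = [
    "acrania", "blepharitis", "carditis", "dactyly", "ectopia", "fibroma",
    "gliosis", "hydrops", "ichthyosis", "keratosis", "lipoma", "myopathy",
    "neuritis", "osteopenia", "ptosis", "rhinitis", "sclerosis", "tremor",
    "uveitis", "vasculitis",
]
_DEF_VOCAB = [
    "abnormality", "tissue", "observed", "patients", "chronic", "onset",
    "bilateral", "severity", "progression", "lesion",
]


def generate_ontology(spec: OntologySpec) -> tuple[str, dict]:
    """Generate OBO text plus a ground-truth match table.

    The truth table maps each planted probe word to the ``(term_id, field)``
    pairs that should match it, so suggester behaviour (including
    definition-only and synonym-only matches) is checkable without parsing
    the generated text again.
    """
    if spec.n_terms < 0:
        raise FixtureSpecError("n_terms must be >= 0")
    if not 0.0 <= spec.synonym_rate <= 1.0:
        raise FixtureSpecError("synonym_rate must be in [0, 1]")
    if not 0.0 <= spec.parent_density <= 1.0:
        raise FixtureSpecError("parent_density must be in [0, 1]")
    plant_words = {w for w, _ in spec.definition_plants} | {
        w for w, _ in spec.synonym_plants
    }
    clash = plant_words & set(_NAME_VOCAB)
    if clash:
        raise FixtureSpecError(f"plant words collide with name vocabulary: {clash}")
    for w, i in spec.definition_plants + spec.synonym_plants:
        if not 0 <= i < spec.n_terms:
            raise FixtureSpecError(f"plant target {i} out of range for {w!r}")

    rng = random.Random(spec.seed)
    term_ids = [f"{spec.id_prefix}:{i + 1:07d}" for i in range(spec.n_terms)]
    def_plants: dict[int, list[str]] = {}
    for w, i in spec.definition_plants:
        def_plants.setdefault(i, []).append(w)
    syn_plants: dict[int, list[str]] = {}
    for w, i in spec.synonym_plants:
        syn_plants.setdefault(i, []).append(w)

    lines = ["format-version: 1.2", ""]
    truth: dict[str, list[tuple[str, str]]] = {w: [] for w in plant_words}
    for i, term_id in enumerate(term_ids):
        a, b = rng.sample(_NAME_VOCAB, 2)
        name = f"{a} with {b}"
        lines.append("[Term]")
        lines.append(f"id: {term_id}")
        lines.append(f"name: {name}")
        def_words = rng.sample(_DEF_VOCAB, 3) + def_plants.get(i, [])
        lines.append(f'def: "{" ".join(def_words)}" []')
        for w in def_plants.get(i, []):
            truth[w].append((term_id, "definition"))
        if i in syn_plants or rng.random() < spec.synonym_rate:
            syn = f"{b} {a}" + "".join(f" {w}" for w in syn_plants.get(i, []))
            lines.append(f'synonym: "{syn}" EXACT []')
            for w in syn_plants.get(i, []):
                truth[w].append((term_id, "synonym"))
        if i > 0 and rng.random() < spec.parent_density:
            parent = term_ids[rng.randrange(i)]
            lines.append(f"is_a: {parent} ! parent")
        lines.append("")
    obo_text = "\n".join(lines)
    return obo_text, {"matches": truth, "term_ids": term_ids}


def parse_generated_ontology(obo_text: str) -> OntologyCollection:
    """Convenience: parse generated OBO text (must always parse cleanly)."""
    import io

    return parse_obo(io.StringIO(obo_text))
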