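"""Sensitivity-encoded query expansion.

A selected phenotype name may be too restrictive as an exact conjunction of
its words — e.g. relaxing *progressive external ophthalmoplegia* to
*progressive ophthalmoplegia* admits additional articles. For each selected
phenotype this module enumerates every non-empty subset of its
stopword-filtered words, counts the documents matching each subset
conjunctively (uncapped — the display cap applies to the heatmap only), and
reports the count, the delta over the full word set ("additional articles"),
and a bar fraction for visual encoding. Dropping words can only grow the
conjunctive match set, so deltas are always non-negative.

Combinations are enumerated per phenotype; the pooled word union across
phenotypes is used only for the heatmap columns, not expanded here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from ._text import tokenize
from .config import DEFAULT_STOPWORDS
from .index import CorpusIndex, count_matching

DEFAULT_WORD_LIMIT = 6


@dataclass
class PhenotypeSelection:
    """Ordered phenotype selections and their pooled distinct words."""

    selections: list[tuple[str, str]]  # (term_id, name)
    words: list[str] = field(default_factory=list)

    @classmethod
    def from_phenotypes(
        cls,
        phenotypes: Iterable[tuple[str, str]],
        stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    ) -> "PhenotypeSelection":
        selections = list(phenotypes)
        pooled: list[str] = []
        for _, name in selections:
            for w in phenotype_words(name, stopwords):
                if w not in pooled:
                    pooled.append(w)
        return cls(selections=selections, words=pooled)


@dataclass
class CombinationRow:
    """One sensitivity-encoded subset of a phenotype's words."""

    term_id: str
    combo: tuple[str, ...]
    count: int
    additional: int  # count minus the full-word-set count of its phenotype
    bar_fraction: float  # count / max count over the emitted rows


def phenotype_words(
    name: str, stopwords: frozenset[str] = DEFAULT_STOPWORDS
) -> list[str]:
    """Normalized, stopword-filtered, deduplicated words of a phenotype name.

    E.g. *congenital fibrosis of extraocular muscles* keeps 4 words — "of"
    is not a query term. A name reducing to zero words is an error.
    """
    words: list[str] = []
    for tok in tokenize(name):
        if tok not in stopwords and tok not in words:
            words.append(tok)
    if not words:
        raise ValueError(f"phenotype name reduces to no query words: {name!r}")
    return words


def enumerate_combinations(
    words: Sequence[str], limit: int = DEFAULT_WORD_LIMIT
) -> list[tuple[str, ...]]:
    """All 2**n - 1 non-empty subsets of *words*.

    Ordered by subset size descending (the full set first), then
    lexicographically by position of the constituent words. More than
    *limit* words is refused — select phenotypes individually instead of
    expanding a pooled union.
    """
    n = len(words)
    if n == 0:
        raise ValueError("no words to combine")
    if n > limit:
        raise ValueError(
            f"{n} words exceeds the combination limit of {limit}; "
            "expand each phenotype separately"
        )
    out: list[tuple[str, ...]] = []
    for size in range(n, 0, -1):
        out.extend(combinations(words, size))
    return out


def expansion_table(
    index: CorpusIndex,
    selection: PhenotypeSelection,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    word_limit: int = DEFAULT_WORD_LIMIT,
) -> list[CombinationRow]:
    """Sensitivity-encoded selector rows for every selected phenotype.

    Per phenotype: one row per non-empty subset of its words, counted
    conjunctively without a cap; ``additional`` is the row count minus the
    full-set count of the same phenotype (0 for the full set itself);
    ``bar_fraction`` normalizes counts to the maximum over all emitted rows.
    """
    if not selection.selections:
        raise ValueError("empty phenotype selection")
    rows: list[CombinationRow] = []
    for term_id, name in selection.selections:
        words = phenotype_words(name, stopwords)
        combos = enumerate_combinations(words, word_limit)
        full_count = count_matching(index, words)
        for combo in combos:
            count = count_matching(index, combo)
            rows.append(
                CombinationRow(
                    term_id=term_id,
                    combo=combo,
                    count=count,
                    additional=count - full_count,
                    bar_fraction=0.0,
                )
            )
    max_count = max((r.count for r in rows), default=0)
    if max_count > 0:
        for r in rows:
            r.bar_fraction = r.count / max_count
    return rows
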