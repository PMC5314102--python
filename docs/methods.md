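# Methods

This note records the models, parameters and design choices behind
`ontotriage`, and what the synthetic test conditions do and do not show.

## Text normalization

One normalizer is shared by every matching surface (suggester, corpus index,
expansion counters, heatmap, distribution matrix, abstract encoder):
lowercase, split on runs of non-alphanumeric characters, no stemming and no
spelling normalization. Sharing it is what makes the cross-view conservation
property hold exactly: a match found in the heatmap is re-findable, with the
same count, in the distribution matrix and the encoded abstract. The cost of
no stemming is that orthographic variants (e.g. *ophthalmoplegia* /
*opthalmoplegia*) are distinct tokens; the sensitivity-expansion mechanism
is the intended remedy, since it lets users see counts for relaxed word
combinations instead of relying on fuzzy matching.

## Ontology suggestion

OBO 1.2/1.4 flat files are parsed by a line-oriented parser that keeps
exactly the fields the engine uses (id, name, def, synonym, comment, is_a,
is_obsolete), strips synonym scope qualifiers to bare text, retains obsolete
terms flagged but never indexes them, reports dangling is_a targets, and has
a canonical writer so parse→write→parse is the identity on those fields.
Parse errors name the offending line. OWL input is out of scope.

Suggestion matching treats the query's last word as a token prefix (the
query is re-run per keystroke) and earlier words as whole tokens; a term
qualifies only if every query word matches in some indexed field. Ranking
sums per-field weights over the matched fields — defaults name 4, synonym 3,
definition 2, comment 1, ties broken by term accession ascending — encoding
the judgement that a label hit is stronger evidence than a commentary hit.
The weights and the result limit (default 25) are configurable; nothing in
the engine depends on their exact values beyond the ordering
name > synonym > definition > comment. Extending a prefix can only shrink
the result set, which the suite verifies exhaustively over the fixture
vocabulary.

## Corpus index and ranking

The index is field-aware: raw counts are kept per (token, document, field)
for the four text places of a citation — title, journal name, MeSH headings,
abstract — because the triage views need them. Scoring pools the four fields
into one bag per document with no per-field boosts: boosts are a tuning
surface with no principled defaults at this corpus scale, and keeping
scoring flat makes the ranker exactly reproducible by a few lines of
brute force (which the tests do, to 1e-9).

The weighting is the classic dampened-tf variant of tf-idf with cosine
normalization: document weight √tf · idf, idf = 1 + ln(N/(1+df)) (smoothed,
so it is defined for unseen tokens and never zero), query weight idf,
score = cosine. Duplicate query tokens collapse before scoring, so scores
are invariant to query order and repetition. Document frequency is
document-level: a token in both title and abstract of one document counts
once.

Search is conjunctive by default — the triage workflow's semantics — with
ties broken by PMID descending (newer citations first; PMIDs are assigned
roughly chronologically). The display cap defaults to 250 documents and
applies to ranked retrieval for the heatmap only; sensitivity-expansion
counts are always computed uncapped, since their purpose is to report true
result-set sizes.

## Sensitivity expansion

Phenotype names are stopword-filtered (fixed English list, configurable)
before combination generation — *congenital fibrosis of extraocular
muscles* contributes 4 query words, not 5. All 2ⁿ−1 non-empty subsets are
enumerated per phenotype (not over the cross-phenotype union, which is used
only for heatmap columns), ordered by size descending then positionally.
A per-phenotype limit of 6 words (64 subsets, hence 63 index lookups)
bounds the exponential blow-up; real phenotype names rarely exceed 4
content words. `additional = count(subset) − count(full set)` is
non-negative by anti-monotonicity of conjunctive matching; bar fractions
are linear in count, normalized to the largest emitted row.

## Triage data model

Heatmap cell saturation is per-column: count divided by the column maximum
over the displayed rows, so each word's densest document is fully saturated
and zero count is exactly white. Per-column (rather than global)
normalization keeps rare-but-informative words visible next to frequent
ones. Column color indices are positions in the pooled query-word list and
are the single source of truth for the distribution matrix and the encoded
abstract.

Dwell accumulates per document across repeat visits; a document is marked
visited exactly when its accumulated dwell reaches the threshold (default
5 s). Accumulation was chosen over requiring a single continuous pause
because the marks exist to answer "have I looked at this?", and three
two-second glances are at least as much exposure as one six-second pause.

The session state machine has three stages; advancing requires a non-empty
selected pile (stage 1→2) and a reading focus (stage 2→3); retreat to any
earlier stage preserves all state. Stage-1 rejection is simply
never-selecting; an explicit reject (remove from pile, clearing the reading
focus if it pointed there) exists at stage 2. The cursor clamps at list
ends. Sessions serialize to versioned JSON so CLI runs can persist them.
Stage payloads are deterministic functions of the session and index, which
makes replaying an event script byte-reproducible — the property the fuzz
and workflow tests pin down.

## Synthetic fixtures

The generator emulates the statistical skeleton of a citation corpus: a
small vocabulary placed into the four text fields with configurable
placement probabilities (defaults title 0.25, journal 0.05, mesh 0.20,
abstract 0.50), background word document-frequencies following a Zipf-like
rank schedule (df ≈ n_docs/2r) for realistic idf spread, and — the point of
the module — *exactly* planted conjunctive co-occurrence counts. Planted
words are reserved: a document assigned to planted set S contains exactly
S's planted words, so the count for any planted set T is the sum of
assignments over supersets of T; the per-set assignments are solved from
the requested counts (largest sets first) and any inconsistency (a superset
requesting more documents than a subset) is rejected before generation.
Ground-truth tables record every token's per-field count per document, so
index statistics are verifiable without re-deriving from text.

What the fixtures do **not** emulate: real MEDLINE scale (tens of millions
of documents), natural-language word burstiness and correlation, structured
abstracts, real MeSH vocabulary, or real HPO content and graph shape.
Passing tests therefore demonstrate correctness of the mechanisms (exact
counts, ranking formulas, state transitions, conservation between views),
not retrieval quality on real literature.

All generator randomness flows through the single seed in each spec; the
same seed gives byte-identical output.

## Problem sizes and numerics

The test suite and the acceptance script run on corpora of 5–1,100
documents and ontologies of 5–40 terms — large enough to exercise the
display cap (1,000 planted matches against the 250-row heatmap), small
enough that every statistic is recomputable by naive scans within the
suite. Score agreement with the brute-force oracle is asserted to 1e-9
(double-precision cosine over short vectors; observed error is at the
machine-epsilon level). Degenerate inputs are defined rather than special-
cased where a sensible meaning exists (empty corpus → empty index; empty
hit list → 0-row heatmap; empty suggestion query → empty list) and errors
where none does (empty search query, phenotype names reducing to zero
words, inconsistent planted counts).

## Known limitations

- Exact token matching only: no stemming, fuzzy matching, or synonym-based
  query expansion (ontology synonyms are used for suggestion, not search).
- Scoring reproduces the standard dampened-tf/smoothed-idf cosine, not any
  particular production engine's quirks (field boosts, coordination
  factors, length pivots).
- The corpus is metadata plus abstract; full text is out of scope.
- The triage engine is headless by design: it emits counts, saturations,
  color indices and spans, never pixels.
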