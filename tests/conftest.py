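"""Shared fixtures: a hand-written mini ontology, a 5-document corpus with
known text, and generated corpora with planted co-occurrence structure."""

from __future__ import annotations

import io

import pytest

from ontotriage import (
    Citation,
    CorpusSpec,
    build_corpus_index,
    build_suggester,
    generate_corpus,
    parse_obo,
)

MINI_OBO = """\
format-version: 1.2
! a comment line

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0001392
name: Abnormality of the liver
is_a: HP:0000001 ! All

[Term]
id: HP:0002240
name: Hepatomegaly
def: "Abnormally increased size of the liver." [HPO:curator]
synonym: "Enlarged liver" EXACT []
is_a: HP:0001392 ! Abnormality of the liver

[Term]
id: HP:0001541
name: Ascites
def: "Accumulation of fluid in the abdominal cavity, commonly associated with liver disease." []
comment: Distinguish from simple abdominal distension.
is_a: HP:0000001

[Term]
id: HP:0009999
name: Retired phenotype
is_obsolete: true
"""


@pytest.fixture(scope="session")
def mini_collection():
    return parse_obo(io.StringIO(MINI_OBO))


@pytest.fixture(scope="session")
def mini_suggester(mini_collection):
    return build_suggester(mini_collection)


@pytest.fixture(scope="session")
def five_doc_citations():
    """Five hand-written citations with known per-field term structure."""
    return [
        Citation(
            pmid=11,
            title="Renin levels in progressive hypertension",
            abstract="Renin and renin receptor levels rise with arterial pressure.",
            journal="Journal of Hypertension",
            year=2001,
            mesh_terms=["Renin", "Hypertension"],
            authors=["Alpha A"],
        ),
        Citation(
            pmid=12,
            title="External ophthalmoplegia case series",
            abstract="Progressive external ophthalmoplegia in twelve patients.",
            journal="Ophthalmology Reports",
            year=2005,
            mesh_terms=["Ophthalmoplegia"],
            authors=["Beta B"],
        ),
        Citation(
            pmid=13,
            title="Mitochondrial disease and muscle weakness",
            abstract="Ophthalmoplegia was progressive; fibrosis of extraocular muscles noted.",
            journal="Muscle and Nerve",
            year=2010,
            mesh_terms=["Mitochondrial Diseases", "Oculomotor Muscles"],
            authors=["Gamma C"],
        ),
        Citation(
            pmid=14,
            title="Arterial pressure regulation",
            abstract="",
            journal="Physiology Today",
            year=1999,
            mesh_terms=["Blood Pressure"],
            authors=["Delta D"],
        ),
        Citation(
            pmid=15,
            title="Congenital fibrosis of the extraocular muscles",
            abstract="Congenital fibrosis with progressive ptosis and ophthalmoplegia.",
            journal="Journal of Medical Genetics",
            year=2015,
            mesh_terms=["Fibrosis", "Oculomotor Muscles"],
            authors=["Epsilon E"],
        ),
    ]


@pytest.fixture(scope="session")
def five_doc_index(five_doc_citations):
    return build_corpus_index(five_doc_citations)


@pytest.fixture(scope="session")
def planted_spec():
    """Corpus spec with exact planted conjunctive counts over 4 words."""
    return CorpusSpec(
        n_docs=80,
        vocabulary=["background", "filler", "noise"],
        planted=[
            (("apex", "bole", "crest"), 10),
            (("apex", "bole"), 14),
            (("bole", "crest"), 20),
            (("apex", "bole", "crest", "dune"), 3),
        ],
        seed=42,
    )


@pytest.fixture(scope="session")
def planted_corpus(planted_spec):
    return generate_corpus(planted_spec)


@pytest.fixture(scope="session")
def planted_index(planted_corpus):
    citations, _ = planted_corpus
    return build_corpus_index(citations)
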