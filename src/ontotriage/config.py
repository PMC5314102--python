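"""Runtime configuration with documented defaults.

Every tunable the engine exposes lives here so the command-line tool and the
library agree on defaults: the 250-document display cap for the query result
heatmap, the 5-second dwell threshold for visited marks, the field weights of
the suggestion ranker, the per-phenotype word limit for combinatorial
expansion, and the URL templates for ontology-term and PubMed detail pages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import yaml

DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    """a an and are as at be but by for from has have if in into is it its of
    on or not no that the their then there these this to was were which will
    with""".split()
)

DEFAULT_FIELD_WEIGHTS: dict[str, float] = {
    "name": 4.0,
    "synonym": 3.0,
    "definition": 2.0,
    "comment": 1.0,
}

DEFAULT_TERM_URL_TEMPLATE = "https://hpo.jax.org/app/browse/term/{term_id}"
DEFAULT_PUBMED_URL_TEMPLATE = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"


class ConfigError(ValueError):
    """Raised for invalid configuration values (rejected at startup)."""


@dataclass(frozen=True)
class Config:
    """Engine configuration.

    Attributes
    ----------
    suggestion_limit : int
        Maximum suggestions returned per query (default 25).
    field_weights : mapping
        Additive weights for suggestion ranking, one per indexed ontology
        field; name outranks synonym outranks definition outranks comment.
    heatmap_cap : int
        Maximum documents visualized in the query result heatmap
        (default 250).
    dwell_threshold_s : float
        Accumulated seconds of dwell after which a document gets a visited
        mark (default 5).
    combination_word_limit : int
        Maximum words per phenotype name for combinatorial expansion
        (default 6; bounds the 2**n subset blow-up).
    stopwords : frozenset of str
        Words dropped from phenotype names before expansion.
    term_url_template, pubmed_url_template : str
        URL templates with a single ``{term_id}`` / ``{pmid}`` placeholder.
    seed : int
        Seed for any randomized operation (fixture generation).
    """

    suggestion_limit: int = 25
    field_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_WEIGHTS)
    )
    heatmap_cap: int = 250
    dwell_threshold_s: float = 5.0
    combination_word_limit: int = 6
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    term_url_template: str = DEFAULT_TERM_URL_TEMPLATE
    pubmed_url_template: str = DEFAULT_PUBMED_URL_TEMPLATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.suggestion_limit < 1:
            raise ConfigError("suggestion_limit must be >= 1")
        if self.heatmap_cap < 1:
            raise ConfigError("heatmap_cap must be >= 1")
        if self.dwell_threshold_s < 0:
            raise ConfigError("dwell_threshold_s must be >= 0")
        if not 1 <= self.combination_word_limit <= 16:
            raise ConfigError("combination_word_limit must be in 1..16")
        missing = {"name", "synonym", "definition", "comment"} - set(
            self.field_weights
        )
        if missing:
            raise ConfigError(f"field_weights missing fields: {sorted(missing)}")
        if any(w < 0 for w in self.field_weights.values()):
            raise ConfigError("field_weights must be non-negative")

    def override(self, **kwargs: Any) -> "Config":
        """Return a copy with the given fields replaced (flags beat file)."""
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        if "stopwords" in kwargs:
            kwargs["stopwords"] = frozenset(kwargs["stopwords"])
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        """Load a configuration from a YAML mapping file."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path!r} must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "stopwords" in data:
            data["stopwords"] = frozenset(data["stopwords"])
        return cls(**data)
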