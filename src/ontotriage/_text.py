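"""Shared text normalization.

Every module that matches words against text — the ontology suggester, the
corpus index, the expansion counters and the triage views — goes through the
same normalizer, so a match found in one view is verifiable in every other:
lowercase, split on runs of non-alphanumeric characters, no stemming.
"""

from __future__ import annotations

import re
from typing import Iterator

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens of *text*, in order of appearance."""
    if not text:
        return []
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


def token_spans(text: str) -> Iterator[tuple[str, int, int]]:
    """Yield (lowercased token, start offset, end offset) for each token.

    Offsets index the original string, so ``text[start:end].lower()`` equals
    the yielded token.
    """
    for m in _TOKEN_RE.finditer(text or ""):
        yield m.group(0).lower(), m.start(), m.end()
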