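"""Shared tokenization used by the dictionary matcher and the lexicon.

Tolerant dictionary matching ignores case and hyphen/space/fused
separator variation.  Both sides (synonyms and scanned text) are
therefore reduced to the same normalized token stream: maximal
alphanumeric runs, further split at letter/digit boundaries (so
"IL6" and "IL-6" both become ["il", "6"]), lowercased.
"""

from __future__ import annotations

import re

_TOKEN_RE = re.compile(r"[A-Za-z]+|[0-9]+")

#: joiner for normalized token keys; never occurs in tokens
SEP = "\x00"


def tokenize(text: str) -> list[tuple[int, int, str]]:
    """Normalized tokens of ``text`` as (start, end, lowercased token)."""
    return [(m.start(), m.end(), m.group(0).lower())
            for m in _TOKEN_RE.finditer(text)]


def norm_key(text: str) -> str:
    """Separator- and case-insensitive key for a synonym or phrase."""
    return SEP.join(tok for _, _, tok in tokenize(text))
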