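"""Gene-symbol normalization shared by the edge-list, GMT and mapping readers.

Normalization is deliberately mechanical: uppercase, Greek-letter
transliteration (as used in protein names such as GSK3β → GSK3B) and removal
of internal whitespace and hyphens.  No alias-database resolution is
attempted; symbols that differ beyond these transformations are distinct
nodes.
"""

from __future__ import annotations

import re

# Greek letters that occur in protein/analyte names, mapped to the Latin
# letter used in the corresponding HGNC-style symbol (theta -> Q as in PRKCQ).
_GREEK = {
    "α": "A", "Α": "A",
    "β": "B", "Β": "B",
    "γ": "G", "Γ": "G",
    "δ": "D", "Δ": "D",
    "θ": "Q", "Θ": "Q",
    "κ": "K", "Κ": "K",
}

_GREEK_TABLE = str.maketrans(_GREEK)
_STRIP = re.compile(r"[\s\-]+")


def normalize_symbol(symbol: str) -> str:
    """Return the canonical form of a gene symbol.

    Idempotent: ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.
    """
    s = symbol.strip().translate(_GREEK_TABLE)
    s = _STRIP.sub("", s)
    return s.upper()
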