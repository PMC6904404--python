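"""Surface-form normalization shared by concept and gazetteer lookups.

All term, city and facility matching in the package is exact on *normalized*
forms: Unicode-decomposed, diacritics stripped, casefolded, internal
whitespace collapsed.  The same function backs the autosuggest prefix index,
so "Ataque al corazón" and "ataque al corazon" index identically.
"""

from __future__ import annotations

import unicodedata

__all__ = ["normalize"]


def normalize(text: str) -> str:
    """Normalize a surface string for matching.

    NFKD-decompose, drop combining marks (diacritics), casefold, and
    collapse runs of whitespace to single spaces.  Idempotent.
    """
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return " ".join(stripped.casefold().split())
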