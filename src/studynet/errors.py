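"""Exception hierarchy.

``StudyNetError`` is the common base; parse errors (malformed input files)
and validation errors (well-formed input violating a contract) are kept
distinct so callers and the CLI can map them to different exit codes.
"""

from __future__ import annotations

__all__ = [
    "StudyNetError",
    "CorpusParseError",
    "CorpusValidationError",
    "ConceptTableError",
    "GazetteerError",
    "FixtureSpecError",
]


class StudyNetError(Exception):
    """Base class for all package-specific errors."""


class CorpusParseError(StudyNetError):
    """Malformed trial or citation XML; the message names the position."""


class CorpusValidationError(StudyNetError):
    """Well-formed record violating an invariant (e.g. missing NCT id)."""


class ConceptTableError(StudyNetError):
    """Bad row in the pipe-delimited concept table."""


class GazetteerError(StudyNetError):
    """Bad row in the tab-separated gazetteer."""


class FixtureSpecError(StudyNetError):
    """Inconsistent synthetic-corpus specification."""
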