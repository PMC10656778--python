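"""Exception hierarchy shared across the package."""


class RefstabError(Exception):
    """Base class for all refstab-specific errors."""


class TableFormatError(RefstabError, ValueError):
    """A delimited table is empty or structurally malformed."""


class IdentifierError(RefstabError, ValueError):
    """Duplicate or otherwise invalid gene/sample identifiers."""


class TableValueError(RefstabError, ValueError):
    """A cell value violates a domain invariant (negative FPKM, Ct out of range, ...)."""


class JoinError(RefstabError, KeyError):
    """Sample metadata does not cover the Ct table (or vice versa)."""


class DimensionError(RefstabError, ValueError):
    """Too few genes or samples for the requested operation."""


class GroupingError(RefstabError, ValueError):
    """Invalid sample grouping (e.g. a group with a single biological sample)."""


class CoverageError(RefstabError, ValueError):
    """Stability tables being aggregated do not cover identical gene sets."""
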