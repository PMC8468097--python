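"""Exception hierarchy shared across the package.

All communet errors derive from :class:`CommunetError` so callers can catch
one base class; the three subclasses separate malformed files, data that
parses but violates a domain rule, and API misuse.
"""


class CommunetError(Exception):
    """Base class for all communet errors."""


class FormatError(CommunetError):
    """A file does not follow the expected dialect (missing column, bad row)."""


class ValidationError(CommunetError):
    """Parsed data violates a domain invariant (duplicates, dangling ids...)."""


class ContractError(CommunetError):
    """An operation was called with arguments violating its preconditions."""
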