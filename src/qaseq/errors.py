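"""Exception hierarchy shared across qaseq modules."""


class QaseqError(Exception):
    """Base class for all qaseq errors."""


class PanelFormatError(QaseqError):
    """Panel table is malformed (missing columns, unparsable fields)."""


class PanelValidationError(QaseqError):
    """Panel table parsed but violates a panel invariant."""


class DomainError(QaseqError, ValueError):
    """An argument is outside the mathematical domain of an operation."""
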