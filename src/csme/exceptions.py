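"""Exception hierarchy for the csme package."""


class CsmeError(Exception):
    """Base class for all csme errors."""


class InvalidArgumentError(CsmeError, ValueError):
    """An argument is outside its documented domain."""


class SchemaError(CsmeError, ValueError):
    """A table is structurally malformed (columns, IDs, duplicates)."""


class BetaValidationError(CsmeError, ValueError):
    """Beta values or proportions violate their numeric bounds."""


class AlignmentError(CsmeError, ValueError):
    """Two inputs that must share sample/CpG keys do not overlap."""


class DegenerateDesignError(CsmeError, ValueError):
    """A regression design has no variance in the predictor."""


class UndefinedResultError(CsmeError, ValueError):
    """A summary statistic is undefined for the given input (e.g. empty)."""
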