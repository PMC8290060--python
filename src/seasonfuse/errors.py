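"""Exception types shared across the pipeline."""


class SeasonFuseError(Exception):
    """Base class for all package errors."""


class FormatError(SeasonFuseError):
    """Malformed input file (missing column, non-numeric content, empty table)."""


class AlignmentError(SeasonFuseError):
    """Sample sets of two tables/blocks do not match."""


class DegenerateInputError(SeasonFuseError):
    """Input is technically valid but the operation is undefined on it
    (all-zero spectrum, all-constant block, zero-sum row, ...)."""


class InvalidFormulaError(SeasonFuseError):
    """Elemental formula string could not be parsed or uses unsupported elements."""
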