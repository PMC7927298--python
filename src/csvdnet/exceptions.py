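"""Exception hierarchy shared across the package."""


class CsvdNetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CsvdNetError, ValueError):
    """Raised when an input file does not have the expected layout."""


class ValidationError(CsvdNetError, ValueError):
    """Raised when values violate a documented contract (negative weights,
    mismatched shapes, out-of-range probabilities, collinear designs...)."""


class UndefinedMetricError(CsvdNetError, ValueError):
    """Raised when a quantity is mathematically undefined for the input
    (e.g. median edge weight of an edgeless graph)."""
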