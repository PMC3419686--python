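"""Exception hierarchy used across the package."""


class GutnetError(ValueError):
    """Base class for all package-specific errors."""


class FormatError(GutnetError):
    """Malformed input table (bad counts, duplicate ids, missing columns)."""


class DegenerateSampleError(GutnetError):
    """A sample has zero total reads and cannot be normalised."""


class AlignmentError(GutnetError):
    """Two objects that must share an index (taxa, samples) do not."""


class UndefinedStatisticError(GutnetError):
    """A statistic is undefined for the given input (constant vector, empty class)."""
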