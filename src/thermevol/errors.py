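"""Exception hierarchy."""


class ThermevolError(Exception):
    """Base class for all package errors."""


class NewickParseError(ThermevolError):
    """Malformed Newick input (unbalanced parentheses, duplicate tips,
    missing branch lengths, ...)."""


class TreeError(ThermevolError):
    """Structural problem with a phylogeny or a pruning request."""


class ParameterError(ThermevolError):
    """Model parameter outside its admissible range."""


class NumericalError(ThermevolError):
    """Linear-algebra failure (singular covariance after jitter, ...)."""


class DegenerateTraitError(ThermevolError):
    """Trait vector carries no variance; the ML variance is zero."""


class DataError(ThermevolError):
    """Malformed tabular input (non-numeric values, bad coordinates, ...)."""
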