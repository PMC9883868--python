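"""Exception hierarchy.

Validation problems (bad inputs, schema violations) derive from
:class:`ValidationError`; failures arising during a computation on
otherwise-valid input derive from :class:`ComputationError`.  The CLI maps
these to exit codes 2 and 3 respectively.
"""


class EndodivError(Exception):
    """Base class for all package errors."""


class ValidationError(EndodivError, ValueError):
    """Input fails a precondition or an invariant."""


class SchemaError(ValidationError):
    """A tabular input is missing or mangling a required column."""


class EmptyStratumError(ValidationError):
    """A (plant, tissue) filter matched zero isolates; indices are undefined."""


class ComputationError(EndodivError, RuntimeError):
    """A stage failed on validated input."""


class IncomparablePairError(ComputationError):
    """A sequence pair shares no comparable (ungapped, unambiguous) site."""


class SaturationError(ComputationError):
    """A distance correction is undefined (divergence beyond the model's range)."""


class InsufficientTaxaError(ValidationError):
    """Fewer than three taxa; no unrooted tree exists."""
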