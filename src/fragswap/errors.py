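"""Exception hierarchy shared by all fragswap modules."""


class FragswapError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FragswapError):
    """A file violates its declared on-disk format."""


class AlphabetError(FormatError):
    """A sequence contains a character outside its molecule alphabet."""


class SchemaError(FormatError):
    """A delimited table is missing required columns for its assay kind."""


class InputError(FragswapError):
    """Semantically invalid input to an operation (empty sequence, too short, ...)."""


class LookupFailure(FragswapError, KeyError):
    """A requested entity (model, chain, fragment) does not exist."""


class FeasibilityError(FragswapError):
    """A requested demarcation objective cannot be satisfied.

    Carries ``max_achievable``: the largest fragment count any valid
    scheme can reach under the same constraints.
    """

    def __init__(self, message: str, max_achievable: int | None = None):
        super().__init__(message)
        self.max_achievable = max_achievable


class ConsistencyError(FragswapError):
    """Two inputs that must agree (e.g. a CDS and its protein) do not."""


class GeometryError(FragswapError):
    """A geometric precondition fails (junction too close to an end, ...)."""


class FitError(FragswapError):
    """A regression or curve fit cannot be performed on the given data."""


class DomainError(FragswapError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""
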