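"""Exception types shared across the package."""


class PopdimError(Exception):
    """Base class for all popdim errors."""


class InvalidInputError(PopdimError, ValueError):
    """Input violates a documented precondition."""


class ContractError(PopdimError, ValueError):
    """Caller violated an API contract (e.g. passed uncentered data where
    centered data is required)."""


class DegenerateDataError(PopdimError, ValueError):
    """Data carries no usable signal (zero variance, identical points, ...)."""


class UndefinedIndexError(PopdimError, ValueError):
    """A ratio-based index is undefined for these inputs."""


class InfeasibleError(PopdimError, ValueError):
    """Requested computation cannot be satisfied (e.g. more orthonormal
    vectors than ambient dimensions)."""
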