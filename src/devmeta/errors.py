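"""Exception hierarchy used across the package.

All errors derive from :class:`DevmetaError` so callers can catch the
package's failures with a single except clause while still discriminating
between configuration mistakes, bad data, and infeasible parameters.
"""


class DevmetaError(Exception):
    """Base class for all errors raised by devmeta."""


class ConfigurationError(DevmetaError):
    """A named input (covariate, file key, config entry) is missing or invalid."""


class DegenerateDesignError(DevmetaError):
    """The confound design matrix is rank deficient."""


class InsufficientSampleError(DevmetaError):
    """Too few subjects for the requested estimate."""


class ValidationError(DevmetaError):
    """Data violates a structural invariant (asymmetry, negativity, NaNs, shape)."""


class ParameterError(DevmetaError):
    """A hyperparameter is outside its admissible range for the given data."""
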