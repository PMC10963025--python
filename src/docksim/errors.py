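"""Exception types shared across the package."""


class DocksimError(Exception):
    """Base class for all package errors."""


class ParameterError(DocksimError, ValueError):
    """A model, protocol or estimator parameter is out of its valid range."""


class DataError(DocksimError, ValueError):
    """Input data violate a structural precondition (shape, sign, parse)."""


class FitError(DocksimError, RuntimeError):
    """An estimator or model fit could not produce a usable result."""
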