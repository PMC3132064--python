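"""Exception types shared across the package."""


class TwindiffError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TwindiffError, ValueError):
    """A file does not conform to the expected tab-delimited dialect."""


class ValidationError(TwindiffError, ValueError):
    """Data violate a cohort or matrix invariant."""


class ParameterError(TwindiffError, ValueError):
    """An argument is outside its admissible range."""
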