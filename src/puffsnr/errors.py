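"""Exception types shared across the package."""


class PuffSNRError(Exception):
    """Base class for all package errors."""


class ParameterError(PuffSNRError, ValueError):
    """A model or configuration parameter is non-finite or out of range."""


class DegenerateInputError(PuffSNRError, ValueError):
    """Inputs are formally valid but make the requested quantity undefined."""
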