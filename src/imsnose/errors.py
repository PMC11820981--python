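"""Exception hierarchy shared across the package."""


class IMSNoseError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(IMSNoseError, ValueError):
    """A file or array violates the data-model invariants."""


class ParameterError(IMSNoseError, ValueError):
    """A parameter is outside its admissible range."""


class RIPDetectionError(IMSNoseError, RuntimeError):
    """No usable reactant-ion peak could be located in a spectrum."""


class InjectionDetectionError(IMSNoseError, RuntimeError):
    """The injection point could not be located on the retention axis."""
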