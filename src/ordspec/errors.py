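"""Exception hierarchy shared across the package."""


class OrdspecError(Exception):
    """Base class for all ordspec errors."""


class InvalidInputError(OrdspecError, ValueError):
    """The input data violate a precondition (non-finite values, too short, ...)."""


class ParameterError(OrdspecError, ValueError):
    """A configuration parameter is outside its supported range."""


class DegenerateEnsembleError(OrdspecError, RuntimeError):
    """The surrogate ensemble has zero spread somewhere; the z-test is undefined."""


class GenerationError(OrdspecError, RuntimeError):
    """A synthetic-system generator diverged or failed an internal guard."""
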