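"""Exception hierarchy for the dgei package."""


class DgeiError(Exception):
    """Base class for all dgei errors."""


class InvalidInputError(DgeiError, ValueError):
    """Raised when an input signal, spec or file violates a precondition."""


class ContractError(DgeiError, RuntimeError):
    """Raised when a caller violates an ordering or state contract."""
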