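"""Exception hierarchy shared across the package."""


class CardsegError(Exception):
    """Base class for all package-specific errors."""


class ContractError(CardsegError, ValueError):
    """An argument violates a documented precondition (shape, range, size)."""


class FormatError(CardsegError, IOError):
    """A file could not be read or is not one of the supported formats."""


class LabelEncodingError(CardsegError, ValueError):
    """A stored label value falls outside the declared encoding's value set."""


class ConfigurationError(CardsegError, ValueError):
    """A configuration object is internally inconsistent or infeasible."""


class UndefinedLossError(CardsegError, FloatingPointError):
    """The baseline generalized Dice loss was evaluated on an instance with an
    absent ground-truth class, where its class weights are infinite."""
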