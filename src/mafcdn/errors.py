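"""Exception hierarchy shared across the package."""


class MafcdnError(Exception):
    """Base class for package errors."""


class ValidationError(MafcdnError, ValueError):
    """An input violates a documented precondition or invariant."""


class ShapeError(ValidationError):
    """Spatially misaligned images/masks, or a size incompatible with the model."""


class DegenerateInputError(ValidationError):
    """An input that makes an operation mathematically undefined (e.g. a
    constant image under histogram stretching)."""


class GenerationError(MafcdnError, RuntimeError):
    """The synthetic-scene generator could not satisfy its placement
    constraints within the bounded retry budget."""
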