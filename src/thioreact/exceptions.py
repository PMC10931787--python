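"""Exception hierarchy for thioreact."""


class ThioreactError(Exception):
    """Base class for all thioreact errors."""


class ParseError(ThioreactError):
    """A quantum-chemistry output file could not be parsed."""


class ValidationError(ThioreactError):
    """An input record violates a structural invariant."""


class DescriptorDomainError(ThioreactError):
    """A conceptual-DFT descriptor is undefined for the given inputs
    (e.g. global softness when the fundamental gap is non-positive)."""


class ModelDomainError(ThioreactError):
    """The fitted reactivity model was evaluated outside its domain
    (non-positive logarithm argument, zero local softness sum, ...)."""
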