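"""Exception types shared across the pipeline stages."""


class RadstabError(Exception):
    """Base class for all package-specific errors."""


class InputError(RadstabError, ValueError):
    """Malformed or inconsistent input data (shape mismatch, empty stack, ...)."""


class ParameterError(RadstabError, ValueError):
    """A parameter outside its documented range."""


class DegenerateInputError(RadstabError, ValueError):
    """Input is valid but degenerate for the requested operation
    (e.g. constant image for intensity windowing, empty ROI)."""


class UndefinedDivergenceError(RadstabError, ValueError):
    """KL uncertainty separability is undefined (no misclassified voxels);
    deliberately distinct from a divergence of zero."""


class IncompleteDesignError(RadstabError, ValueError):
    """A reliability design is missing cells; the message names them."""
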