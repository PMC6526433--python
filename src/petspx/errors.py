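"""Exception hierarchy for the segmentation pipeline.

Exit-code mapping used by the CLI: validation / I/O problems exit with 1,
degenerate inputs (no structure to segment) exit with 2.
"""


class PetspxError(Exception):
    """Base class for all petspx errors."""


class ValidationError(PetspxError, ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(PetspxError):
    """The input carries no structure the method can act on.

    Raised e.g. for a constant image (zero total variance, component
    selection undefined) or a constant distance vector (no separable
    structure for a binary split).
    """
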