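"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero counts)."""


class PlacementFailureError(RuntimeError):
    """Random interval placement could not satisfy the non-overlap constraint."""


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""
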