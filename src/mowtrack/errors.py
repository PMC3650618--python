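"""Exception types shared across the package."""


class FormatError(ValueError):
    """Raised when an on-disk file or table violates its expected format."""


class GridMismatchError(ValueError):
    """Raised when two spatial objects do not live on the same voxel grid."""


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is internally inconsistent."""
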