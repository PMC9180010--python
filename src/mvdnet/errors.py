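"""Exception types raised across the package."""


class MVDNetError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(MVDNetError):
    """An architecture or configuration spec violates its invariants."""


class InvalidInputError(MVDNetError):
    """An input array is incompatible with the requested computation."""


class ShapeError(MVDNetError):
    """Feature-map shapes are inconsistent at a fusion point."""


class SchemaError(MVDNetError):
    """A label value or palette color falls outside the class schema."""
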