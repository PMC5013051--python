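"""Exception types shared across the package."""


class SemgKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SemgKitError):
    """A file or container does not follow the expected dialect
    (e.g. a required field such as ``stimulus`` is missing)."""


class IntegrityError(SemgKitError):
    """A container parsed correctly but its contents are inconsistent
    (e.g. label vectors shorter than the signal matrix)."""


class LayoutMismatchError(SemgKitError):
    """Feature layout at prediction time differs from the layout a model
    was trained on."""
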