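"""Exception types shared across the package."""


class AutofluorError(Exception):
    """Base class for all domain errors."""


class IncompleteBlockError(AutofluorError):
    """A data block is missing one or more channel images."""


class GeometryError(AutofluorError):
    """Image shapes within a block or reference set are inconsistent."""


class UncalibratableChannelError(AutofluorError):
    """A channel's calibration excess (calibration minus water) is nonpositive."""


class CrowdedFieldError(AutofluorError):
    """Synthetic cells could not be placed without overlap after bounded retries."""


class ValidationError(AutofluorError):
    """A domain-type invariant was violated."""
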