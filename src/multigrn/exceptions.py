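"""Exception hierarchy shared across the pipeline."""


class MultigrnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MultigrnError):
    """An invalid configuration value; the message names the field."""


class FormatError(MultigrnError):
    """A malformed on-disk file; the message names the file."""


class AlignmentError(MultigrnError):
    """Cell/feature sets that must agree between objects do not."""


class EmptyResultError(MultigrnError):
    """An operation removed every cell/feature it was given."""
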