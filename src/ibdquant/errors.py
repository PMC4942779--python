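"""Typed errors raised by ibdquant.

Every failure mode that a caller might want to catch has its own class;
readers and pipeline stages never signal problems by silently coercing data.
"""


class IbdQuantError(Exception):
    """Base class for all ibdquant errors."""


class ChannelMissingError(IbdQuantError):
    """An expected modality channel is absent from a sample or image stack."""


class ShapeMismatchError(IbdQuantError):
    """Arrays that must share a pixel grid do not."""


class RoiInconsistentError(IbdQuantError):
    """Crypt pixels fall outside the mucosa mask (policy='error')."""


class InvalidLevelError(IbdQuantError):
    """A histological index level outside its allowed set (e.g. architecture=1)."""


class EmptyRoiError(IbdQuantError):
    """A statistic was requested over an empty region of interest."""


class DegenerateClassesError(IbdQuantError):
    """A two-class computation received fewer than two usable classes."""


class FeatureMismatchError(IbdQuantError):
    """Feature names at predict time do not match the fitted model."""


class PackingError(IbdQuantError):
    """The requested crypt density cannot be realised without overlaps."""
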