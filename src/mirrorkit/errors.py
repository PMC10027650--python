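"""Exception hierarchy for mirrorkit.

All errors derive from :class:`MirrorKitError` so callers can catch the
package's failures with a single except clause while still distinguishing
configuration mistakes from malformed data files.
"""


class MirrorKitError(Exception):
    """Base class for all mirrorkit errors."""


class PipelineSpecError(MirrorKitError, ValueError):
    """A pipeline specification file is empty, malformed, or references an
    unregistered module type."""


class TrackFormatError(MirrorKitError, ValueError):
    """A face-state track CSV is missing required columns or is otherwise
    unreadable."""


class ConfigurationError(MirrorKitError, ValueError):
    """A module or schedule was configured inconsistently (e.g. baseline
    replay requested without a replay source)."""


class SessionStateError(MirrorKitError, RuntimeError):
    """A control command was issued to a session that is not running."""
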