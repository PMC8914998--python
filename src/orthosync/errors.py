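"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`OrthosyncError`, so callers can catch one type at a pipeline
boundary (the CLI does exactly that).
"""


class OrthosyncError(Exception):
    """Base class for all orthosync errors."""


class DialectError(OrthosyncError):
    """A file does not match the expected instrument-export dialect."""


class IntegrityError(OrthosyncError):
    """A parsed file violates a structural invariant (e.g. non-monotone time)."""


class ManifestError(OrthosyncError):
    """Channels disagree with the channel manifest (duplicates, wrong set)."""


class SyncError(OrthosyncError):
    """Event-marker alignment cannot be performed."""


class ScheduleError(OrthosyncError):
    """An assessment schedule is internally inconsistent."""


class ChannelError(OrthosyncError):
    """A requested channel does not exist in the frame."""


class ConfigError(OrthosyncError):
    """Invalid simulator or detector configuration."""


class InputError(OrthosyncError):
    """An input series is unusable (e.g. shorter than the analysis window)."""


class PlotSpecError(OrthosyncError):
    """A plot specification is empty or inconsistent with the data."""
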