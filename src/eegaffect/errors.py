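"""Typed exceptions raised across the pipeline."""


class EEGAffectError(Exception):
    """Base class for all package errors."""


class ChannelMismatchError(EEGAffectError):
    """A file's channels do not cover the requested montage."""


class LabelError(EEGAffectError):
    """Trial labels missing or unreadable."""


class FeatureUndefinedError(EEGAffectError):
    """A feature is mathematically undefined on the given input
    (zero-variance signal, zero spectral energy, missing IMF, ...)."""


class MissingIMFError(FeatureUndefinedError):
    """The decomposition produced fewer IMFs than the requested index."""


class MetricUndefinedError(EEGAffectError):
    """A metric cannot be computed (e.g. Pearson r on a constant series)."""
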