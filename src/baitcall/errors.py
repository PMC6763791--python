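"""Exception hierarchy for the baitcall pipeline.

Every stage raises a subclass of :class:`BaitcallError` so that the
pipeline driver can abort with the failing stage's name and cause while
keeping partial outputs on disk.
"""


class BaitcallError(Exception):
    """Base class for all baitcall errors."""


class ConfigurationError(BaitcallError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(BaitcallError):
    """A malformed input file; the message carries the file/row context."""


class ModelError(BaitcallError):
    """The background null model could not be built or fitted."""


class ParameterError(BaitcallError):
    """A numeric parameter outside its documented range."""


class DataError(BaitcallError):
    """Inconsistent data handed between stages (e.g. frequency outside [0, 1])."""


class QCError(BaitcallError):
    """Replicate quality control could not be computed."""


class GenerationError(BaitcallError):
    """The synthetic-data generator could not satisfy the request."""
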