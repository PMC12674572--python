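"""Exception hierarchy.

Scientific precondition violations (bad parameters, too-short series,
misaligned cohorts) are kept distinct from I/O failures so the CLI can map
them to exit codes 1 and 2 respectively.
"""


class AccelharmError(Exception):
    """Base class for all scientific-precondition errors."""


class StructuralError(AccelharmError):
    """Malformed in-memory data (unequal axis lengths, empty groups)."""


class ParameterError(AccelharmError):
    """A parameter violates an operation precondition."""


class ConfigurationError(AccelharmError):
    """A configuration resource is incomplete or inconsistent."""


class TooShortError(AccelharmError):
    """A series is too short to survive the requested trimming."""


class AlignmentError(AccelharmError):
    """Second-level series are not aligned across locations/metrics."""
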