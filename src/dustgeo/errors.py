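"""Named exception classes for the attribution pipeline."""


class DustgeoError(Exception):
    """Base class for all package errors."""


class ParseError(DustgeoError):
    """Malformed input file (missing columns, duplicate ids, absent FASTA record)."""


class SampleMismatchError(DustgeoError):
    """Tables combined across markers do not share a sample id."""


class OffGridError(DustgeoError):
    """A required coordinate (e.g. the truth point) falls outside the grid extent."""


class NoMappedOtusError(DustgeoError):
    """No OTU in the sample produced a non-empty gridded distribution."""


class EmptySurfaceError(DustgeoError):
    """Mixture fitting requested on a surface with no nonzero cell."""
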