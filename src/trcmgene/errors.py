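"""Exception hierarchy for the trcmgene package.

All library errors derive from :class:`TrcmgeneError` so callers (and the
command-line interface) can distinguish corruption (exit code 1) from usage
and format problems (exit code 2).
"""


class TrcmgeneError(Exception):
    """Base class for all trcmgene errors."""


class FormatError(TrcmgeneError):
    """Malformed input file (PED/MAP/TSV parsing problems)."""


class ParameterError(TrcmgeneError):
    """Invalid parameter value (thresholds, cluster counts, quantiles)."""


class AssemblyError(TrcmgeneError):
    """Inconsistent inputs handed to the container writer."""


class CorruptionError(TrcmgeneError):
    """A container file failed a checksum or structural validation."""


class UnsupportedVersionError(CorruptionError):
    """Container format version is newer than this library supports."""


class NotFoundError(TrcmgeneError):
    """A requested individual id is absent from a container index."""
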