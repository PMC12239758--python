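"""Exception hierarchy.

All package errors derive from :class:`KmersigError` so callers can catch
one type at the CLI boundary.
"""


class KmersigError(Exception):
    """Base class for all kmersig errors."""


class ParameterError(KmersigError, ValueError):
    """A parameter is outside its documented range."""


class FastqFormatError(KmersigError):
    """Malformed FASTQ input (truncated record, bad header line)."""


class TableFormatError(KmersigError):
    """Malformed feature-table TSV (bad header, ragged row, NA cell)."""


class MetadataError(KmersigError):
    """Sample metadata problem: missing label, duplicate sample id, mixed k."""


class EmptySampleError(KmersigError):
    """A sample yielded zero valid k-mer windows."""


class UndefinedMetricError(KmersigError):
    """A metric is undefined for the given labels (e.g. single-class ROC)."""


class ConfigError(KmersigError):
    """Pipeline configuration is invalid."""
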