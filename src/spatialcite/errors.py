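"""Exception hierarchy; error classes map to distinct CLI exit codes."""


class SpatialCiteError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(SpatialCiteError):
    """Invalid configuration, layout or whitelist/panel validation failure."""

    exit_code = 2


class InputError(SpatialCiteError):
    """Missing or unreadable input file, truncated/mispaired FASTQ."""

    exit_code = 3


class DataError(SpatialCiteError):
    """Inconsistent data encountered mid-pipeline (unknown feature, bad pixel)."""

    exit_code = 4
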