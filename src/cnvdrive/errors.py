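"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
any other CnvDriveError -> 4.
"""


class CnvDriveError(Exception):
    """Base class for all errors raised by cnvdrive."""


class ConfigError(CnvDriveError):
    """Invalid configuration or missing input file (detected pre-flight)."""


class DataError(CnvDriveError):
    """Malformed input data (bad row, unknown chromosome, broken invariant)."""


class StageError(CnvDriveError):
    """A pipeline stage failed after pre-flight checks passed."""
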