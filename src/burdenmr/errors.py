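"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4; anything else propagates as 1.
"""


class BurdenMRError(Exception):
    """Base class for all package errors."""


class ConfigError(BurdenMRError):
    """Invalid configuration value; the message names the offending field."""


class DataError(BurdenMRError):
    """Malformed or inconsistent input data."""


class AlignmentError(DataError):
    """Tables that must share identifiers do not."""


class NumericalError(BurdenMRError):
    """A fit or statistic could not be computed (degenerate input, rank
    deficiency, non-convergence that cannot be flagged in-band)."""
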