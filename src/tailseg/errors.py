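"""Exception hierarchy shared across the toolkit.

The CLI maps ConfigError to exit code 2 and DataError to exit code 3.
"""


class TailsegError(Exception):
    """Base class for toolkit errors."""


class ConfigError(TailsegError):
    """Invalid configuration (bad field values, infeasible geometry...)."""


class DataError(TailsegError):
    """Invalid or inconsistent data (bad labels, missing files, shapes...)."""
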