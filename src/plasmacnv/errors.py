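"""Exception hierarchy shared across the package.

Each error class carries the process exit code the command-line layer maps
it to (0 success, 2 input/format, 3 insufficient data, 4 configuration).
"""


class PlasmaCNVError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(PlasmaCNVError):
    """Malformed or inconsistent input file."""

    exit_code = 2


class InsufficientDataError(PlasmaCNVError):
    """Too little usable data to run a statistical step."""

    exit_code = 3


class ConfigError(PlasmaCNVError):
    """Invalid or incomplete run configuration."""

    exit_code = 4


class MissingFetalFractionError(ConfigError):
    """A fetal fraction is required but neither estimable nor supplied."""
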