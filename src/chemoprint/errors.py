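"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`ChemoprintError`
so that the CLI can map library errors onto exit codes (2 = configuration,
3 = data) without string matching.
"""


class ChemoprintError(Exception):
    """Base class for all package errors."""


class ConfigError(ChemoprintError):
    """Invalid parameter, option or configuration file (CLI exit code 2)."""


class DataError(ChemoprintError):
    """Invalid or unusable input data (CLI exit code 3)."""


class PeakListParseError(DataError):
    """A peak-list file contained a malformed row; names the line number."""

    def __init__(self, path, line_number, message):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class EmptyInputError(DataError):
    """A file or collection that must contain data was empty."""


class FormatError(DataError):
    """A structured file (e.g. mzML, cluster matrix) did not match its format."""


class CalibrationError(DataError):
    """Mass calibration could not be fitted or applied."""


class NormalizationError(DataError):
    """Spectrum cannot be normalized (e.g. all intensities zero)."""
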