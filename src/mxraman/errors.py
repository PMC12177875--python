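"""Exception hierarchy for the toolkit.

Every error raised by mxraman derives from :class:`MXRamanError` so callers
(and the CLI) can catch toolkit failures without masking programming errors.
"""


class MXRamanError(Exception):
    """Base class for all toolkit errors."""


class SpectrumParseError(MXRamanError):
    """A spectrum text file could not be parsed."""


class OutOfRangeError(MXRamanError):
    """Interpolation outside the recorded wavenumber range was requested."""


class MetadataConflictError(MXRamanError):
    """Inconsistent per-spectrum metadata (e.g. one sample, two class labels)."""


class DatasetFormatError(MXRamanError):
    """A dataset file violates the tabular on-disk format."""


class MissingBlankError(MXRamanError):
    """Background subtraction was requested without any blank spectra."""


class InvalidConfigError(MXRamanError):
    """A configuration value is out of its permitted range."""


class DegenerateInputError(MXRamanError):
    """Input is degenerate for the requested operation (e.g. all-zero spectrum)."""


class InvalidInputError(MXRamanError):
    """Input data violate an operation precondition."""


class PairingError(MXRamanError):
    """Rows of two datasets cannot be paired sample-by-sample."""


class AlignmentError(MXRamanError):
    """Wavenumber axes of two datasets do not match."""


class LabelError(MXRamanError):
    """A requested class label is absent or the class structure is wrong."""


class MappingError(MXRamanError):
    """A barcode variable cannot be resolved in the dataset column map."""


class SchemaError(MXRamanError):
    """Column maps of model and data disagree."""
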