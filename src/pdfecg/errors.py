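"""Exception hierarchy for the digitization pipeline."""


class PdfEcgError(Exception):
    """Base class for all pipeline errors."""


class DocumentError(PdfEcgError):
    """The PDF cannot be opened: corrupt, truncated or encrypted."""


class RasterPageError(PdfEcgError):
    """The page stores the ECG as a pixel image; vector recovery is impossible."""


class LayoutError(PdfEcgError):
    """Fewer than 12 leads could be resolved on the page.

    ``missing`` lists the lead names that could not be placed.
    """

    def __init__(self, message: str, missing: tuple = ()):  # noqa: D107
        super().__init__(message)
        self.missing = tuple(missing)


class ShortStripError(PdfEcgError):
    """A reconstructed trace covers less than 80% of the expected strip."""


class FilterSpecError(PdfEcgError):
    """A filter cutoff is at or above the Nyquist frequency."""


class NoBeatsError(PdfEcgError):
    """No QRS complex could be detected in a lead."""


class MeasurementError(PdfEcgError):
    """A global interval measurement has no usable fiducials."""


class PairingError(PdfEcgError):
    """Paired statistical inputs have mismatched lengths."""


class DegenerateInputError(PdfEcgError):
    """A statistical operator received zero-variance input."""


class StratificationError(PdfEcgError):
    """A diagnosis class has too few patients to hold one out."""


class ShapeError(PdfEcgError):
    """A matrix argument has the wrong shape."""


class EmptyInputError(PdfEcgError):
    """An aggregate was requested over an empty collection."""


class ParamError(PdfEcgError):
    """Synthetic beat-model parameters are inconsistent."""


class UsageError(PdfEcgError):
    """A CLI command was invoked with an empty or invalid input set."""
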