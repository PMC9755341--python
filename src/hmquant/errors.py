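"""Exception hierarchy shared across the package."""


class HMQuantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HMQuantError, ValueError):
    """A domain object violates one of its invariants."""


class GeometryError(HMQuantError, ValueError):
    """Organ/ROI geometry is inconsistent (e.g. empty myocardium mask)."""


class PlacementError(HMQuantError, ValueError):
    """An ROI cannot be placed (square too small, ROI outside image)."""


class EmptyROIError(HMQuantError, ValueError):
    """ROI rasterizes to an empty pixel mask on the target image."""


class LandmarkDetectionError(HMQuantError, RuntimeError):
    """Automatic landmark-square detection failed on this image."""


class FormatError(HMQuantError, ValueError):
    """A file does not parse in the requested dialect."""


class UnsupportedInputError(HMQuantError, ValueError):
    """Input is syntactically valid but outside the supported subset."""


class RangeError(HMQuantError, ValueError):
    """Values exceed the representable range of the output format."""


class SchemaError(HMQuantError, ValueError):
    """A serialized ROI/config document violates the JSON schema."""


class DivisionError(HMQuantError, ZeroDivisionError):
    """Denominator region has zero mean counts."""


class DegenerateInputError(HMQuantError, ValueError):
    """A statistic is undefined for this input (e.g. zero variance)."""


class DegenerateTableError(DegenerateInputError):
    """A contingency table has a zero margin."""


class CompletenessError(HMQuantError, ValueError):
    """External analysis input is missing required subject/rater/method items."""

    def __init__(self, gaps):
        self.gaps = list(gaps)
        msg = "missing input for: " + ", ".join(
            "/".join(str(g) for g in gap) for gap in self.gaps
        )
        super().__init__(msg)
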