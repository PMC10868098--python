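"""Exception hierarchy for fishquant."""


class FishQuantError(Exception):
    """Base class for all fishquant errors."""


class InvalidParameterError(FishQuantError, ValueError):
    """A parameter is outside its allowed domain."""


class CoordinateRangeError(FishQuantError, ValueError):
    """A coordinate lies outside the image field."""


class PlacementError(FishQuantError, RuntimeError):
    """Requested objects could not be placed without overlap."""


class FormatError(FishQuantError, ValueError):
    """A file is not in the expected on-disk format."""


class SchemaError(FishQuantError, ValueError):
    """A table is missing required columns or has invalid values."""


class DimensionError(FishQuantError, ValueError):
    """Array shapes are inconsistent."""


class DegenerateThresholdError(FishQuantError, ValueError):
    """No threshold separates signal from background (e.g. constant image)."""


class RankDeficiencyError(FishQuantError, ValueError):
    """The regression design matrix is rank deficient (collinear predictors)."""


class CalibrationError(FishQuantError, ValueError):
    """A calibration reference value is invalid (e.g. non-positive)."""


class DegenerateTestError(FishQuantError, ValueError):
    """A statistical test is undefined for the given data (e.g. all-zero differences)."""


class DegenerateMarginError(FishQuantError, ValueError):
    """A contingency table has a zero row or column margin."""


class IncompleteInputError(FishQuantError, ValueError):
    """A required input (e.g. an IHC score for groups 2-4) is missing."""
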