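"""Exception and warning types used across the pipeline."""


class GaitpalError(Exception):
    """Base class for all package-specific errors."""


class InputShapeError(GaitpalError):
    """Axis series of unequal length or otherwise malformed array input."""


class ParameterError(GaitpalError):
    """Invalid parameter value (non-positive sampling rate, empty cycle list, ...)."""


class CalibrationQualityError(GaitpalError):
    """Treadmill calibration unusable: no gait periodicity detected."""


class DegenerateCalibrationError(GaitpalError):
    """A classifier feature has zero variance over the calibration epochs."""


class FormatError(GaitpalError):
    """Malformed recording file (bad rows, missing header, inconsistent rate)."""


class NoValidDaysError(GaitpalError):
    """Subject has no valid monitoring days and must be excluded."""


class CalibrationQualityWarning(UserWarning):
    """Calibration is usable but thin (few epochs) or otherwise marginal."""


class CollinearityWarning(UserWarning):
    """Regression design matrix is ill-conditioned."""
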