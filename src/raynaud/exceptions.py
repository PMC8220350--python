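"""Exception hierarchy shared across the pipeline stages."""


class RaynaudError(Exception):
    """Base class for all package-specific errors."""


class VariableNotFoundError(RaynaudError, KeyError):
    """Requested variable is absent from the NetCDF file."""


class UnitsError(RaynaudError, ValueError):
    """Temperature units attribute is missing or unsupported."""


class CalendarError(RaynaudError, ValueError):
    """Time axis is not daily, not unique, or otherwise malformed."""


class CoverageError(RaynaudError, ValueError):
    """Grid time axis does not cover the requested calendar window."""

    def __init__(self, message: str, missing_dates=None):
        super().__init__(message)
        self.missing_dates = list(missing_dates) if missing_dates is not None else []


class NoLandCellError(RaynaudError, ValueError):
    """No unmasked grid cell within the point-extraction search radius."""


class ValidationError(RaynaudError, ValueError):
    """A tabular input row violates its schema constraints."""


class LinkageError(RaynaudError, KeyError):
    """A study site cannot be linked to coordinates."""


class DegenerateDesignError(RaynaudError, ValueError):
    """Regression design matrix is rank deficient or has no variation."""


class DegenerateFitError(RaynaudError, ValueError):
    """Likelihood has no finite maximizer (e.g. all counts zero)."""


class NoCrossingError(RaynaudError, ValueError):
    """Linear prevalence fit has no downward zero crossing."""


class AlignmentError(RaynaudError, ValueError):
    """Two gridded fields do not share lat/lon axes."""


class ConfigError(RaynaudError, ValueError):
    """Pipeline configuration is invalid or references missing files."""


class PlacementError(RaynaudError, ValueError):
    """Synthetic site placement cannot satisfy its constraints."""
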