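"""Exception hierarchy shared across the package."""


class TMTVError(Exception):
    """Base class for all tmtvbench errors."""


class InputFormatError(TMTVError, ValueError):
    """Unreadable, malformed, or geometrically invalid input data."""


class GridMismatchError(TMTVError, ValueError):
    """Two volumes that must share a voxel grid do not."""


class NoComponentAtPointError(TMTVError, ValueError):
    """A removal click landed on background (label 0)."""


class SeedBelowThresholdError(TMTVError, ValueError):
    """An add-lesion seed points at a voxel below the SUV threshold."""


class ScenarioNotFoundError(TMTVError, KeyError):
    """Requested phantom scenario is not in the shipped library."""


class ValidationDataError(TMTVError, ValueError):
    """Measured/reference tables cannot be compared (no shared keys etc.)."""
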