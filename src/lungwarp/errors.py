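"""Exception types shared across the package."""


class LungwarpError(Exception):
    """Base class for package errors."""


class VolumeFormatError(LungwarpError, ValueError):
    """A file could not be read as a supported volume format."""


class DimensionalityError(LungwarpError, ValueError):
    """A volume payload is not three-dimensional."""


class DegenerateInputError(LungwarpError, ValueError):
    """An input is degenerate (constant volume, empty mask, ...)."""


class LandmarkParseError(LungwarpError, ValueError):
    """A landmark file has ragged or non-numeric rows."""


class ContractError(LungwarpError, ValueError):
    """Arguments violate an operation's shape/compatibility contract."""


class TpsSolveError(LungwarpError, RuntimeError):
    """The thin-plate-spline linear system is (near-)singular."""


class ManifestError(LungwarpError, ValueError):
    """A dataset manifest references missing or inconsistent files."""
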