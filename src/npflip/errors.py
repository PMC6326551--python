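"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`NpflipError`
so callers can catch one base class at pipeline boundaries.
"""


class NpflipError(Exception):
    """Base class for all package errors."""


class CompositionError(NpflipError, ValueError):
    """A built system violates a composition rule (charge, stoichiometry)."""


class UnsupportedCaseError(NpflipError, ValueError):
    """A physically meaningful case the package deliberately does not handle."""


class UndefinedMidplaneError(NpflipError, ValueError):
    """The bilayer midplane cannot be estimated (e.g. a one-leaflet frame)."""


class NoEndGroupError(NpflipError, ValueError):
    """An end-group quantity was requested for a ligand without one (OT)."""


class AmbiguousClassificationError(NpflipError, ValueError):
    """A ligand's mean d_z is exactly zero; the caller must break the tie."""


class TerminalStateError(NpflipError, RuntimeError):
    """No ligand with positive d_z remains; the flip sequence has terminated."""


class FlipError(NpflipError, ValueError):
    """A flip was requested for a ligand that cannot be flipped."""


class TopologyMismatchError(NpflipError, ValueError):
    """Two frames that must share a topology do not."""


class ConfigurationError(NpflipError, ValueError):
    """A required parameter (threshold, radius, config key) is missing or bad."""


class NoMinimumError(NpflipError, ValueError):
    """A profile has no first minimum (e.g. monotone g(r))."""


class GroParseError(NpflipError, ValueError):
    """A coordinate file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
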