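"""Exception hierarchy for gqdsense.

Every error raised by the library derives from :class:`GqdError`, so callers
can catch one type at pipeline boundaries while tests discriminate finely.
"""


class GqdError(Exception):
    """Base class for all gqdsense errors."""


class ParseError(GqdError):
    """An interchange stream violated the documented schema."""


class RecordValidationError(GqdError):
    """A record violated a physical or structural invariant."""


class LinkageError(GqdError):
    """A complex link references labels that do not resolve consistently."""


class UnitError(GqdError):
    """A quantity was supplied without, or with an unknown, unit tag."""


class MissingPropertyError(GqdError):
    """An operation needs an optional record field that is absent."""


class DegenerateGeometryError(GqdError):
    """A geometric operator received coincident points / zero-length arms."""


class DegenerateHardnessError(GqdError):
    """Hardness at or below tolerance; softness and ΔNmax are undefined."""


class ConfigurationError(GqdError):
    """An invalid generator spec, run config, or missing reference energy."""
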