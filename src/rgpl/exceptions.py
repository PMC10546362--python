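"""Exception hierarchy.

All package errors derive from :class:`RgplError` so callers can catch one
type; they also derive from :class:`ValueError` so sloppy callers are not
silently broken.
"""


class RgplError(Exception):
    """Base class for all errors raised by this package."""


class InputError(RgplError, ValueError):
    """Invalid data passed to an operation (shape mismatch, bad values, ...)."""


class ConfigurationError(RgplError, ValueError):
    """Invalid parameter or unknown named configuration (e.g. dialect name)."""


class NotAchievableError(RgplError, ValueError):
    """A requested performance target lies above the observed curve."""
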