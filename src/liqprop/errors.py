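"""Exception hierarchy.

Parse/format problems raise :class:`FormatError`; semantically malformed but
parseable inputs raise :class:`StructureError`; bad argument values raise
``ValueError`` subclasses so callers can catch either the specific class or
the builtin.
"""


class LiqpropError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LiqpropError):
    """Input text does not follow the expected file dialect."""


class StructureError(LiqpropError):
    """Input parses but violates a structural invariant (e.g. atom-count drift)."""


class UnitConfigurationError(LiqpropError):
    """A reduced (lj) unit conversion was requested without a reference scale."""


class ValidationError(LiqpropError, ValueError):
    """A document or template fails schema-level validation."""


class DetectionError(LiqpropError):
    """Automatic feature detection (e.g. first RDF minimum) failed."""


class UnsupportedSystemError(LiqpropError):
    """The requested property is not defined for this system composition."""


class ValidityError(LiqpropError):
    """A quantum document fails a physical-validity gate (imaginary frequencies)."""


class StoichiometryError(LiqpropError):
    """Charge or atom bookkeeping does not balance across a reaction."""


class PhaseError(LiqpropError, ValueError):
    """A thermochemistry operation received documents in the wrong phase."""


class CompletenessError(LiqpropError):
    """A computation is missing required state documents; lists what is absent."""
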