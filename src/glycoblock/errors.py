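"""Exception hierarchy shared across the package."""


class GlycoblockError(Exception):
    """Base class for all package errors."""


class ValidationError(GlycoblockError):
    """Input data violates a structural or numeric contract."""


class SchemaError(ValidationError):
    """A file is missing required columns or has malformed structure."""


class IntegrityError(ValidationError):
    """Duplicate identifiers or broken cross-references."""


class FormulaError(ValidationError):
    """A derived-trait formula fails to parse or references unknown peaks."""


class ComputationError(GlycoblockError):
    """A numeric operation cannot proceed (degenerate input, divide by zero)."""
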