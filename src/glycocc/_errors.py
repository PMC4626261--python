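"""Exception hierarchy.

All package errors derive from :class:`GlycoccError` so callers can catch
one base class; most also derive from a matching builtin so generic
``except ValueError`` style handling keeps working.
"""


class GlycoccError(Exception):
    """Base class for all glycocc errors."""


class SchemaError(GlycoccError, ValueError):
    """Input table does not match the expected column schema."""


class IntegrityError(GlycoccError, ValueError):
    """Input violates an integrity constraint (e.g. duplicate sample IDs)."""


class DefinitionError(GlycoccError, ValueError):
    """A derived-trait definition is malformed or inconsistent with the panel."""


class DesignError(GlycoccError, ValueError):
    """Regression design is degenerate (rank deficient, too few df, constant predictor)."""


class SeparationError(GlycoccError, RuntimeError):
    """Logistic fit diverged: complete or quasi-complete separation."""


class StratificationError(GlycoccError, ValueError):
    """A cross-validation fold or classification target lost one of its classes."""


class ConfigError(GlycoccError, ValueError):
    """Run or simulation configuration failed validation."""
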