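"""Exception hierarchy for input validation and configuration errors."""


class GenevoteError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GenevoteError, ValueError):
    """A table or record failed validation; the message names the offender."""


class DesignError(ValidationError):
    """Sample design table inconsistent with the expression matrix."""


class SubgroupSizeError(DesignError):
    """A case or control subgroup is below the minimum size of 3."""


class MatrixError(ValidationError):
    """Expression matrix malformed (non-numeric cell, duplicate probe, ...)."""


class CoordinateError(ValidationError):
    """Genomic coordinate table malformed (start > end, bad position, ...)."""


class ConfigError(GenevoteError, ValueError):
    """A configuration field is out of range or inconsistent."""
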