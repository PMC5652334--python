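"""Named exceptions raised across the package.

Every validation failure maps to a distinct class so callers (and the CLI)
can react specifically instead of string-matching messages.
"""


class ReceptorCallError(Exception):
    """Base class for all package errors."""


class InsufficientClassDataError(ReceptorCallError):
    """Fewer than the minimum number of samples in an IHC class."""


class DegenerateFitError(ReceptorCallError):
    """Mixture fit collapsed: zero variance, sigma below floor, or a
    component claiming responsibility for fewer than two samples."""


class NonIdentifiableError(ReceptorCallError):
    """Observed information matrix is singular (or numerically so)."""


class NoValidCutpointError(ReceptorCallError):
    """Equal-posterior equation has no root between the component means."""


class NoCriticalDomainError(ReceptorCallError):
    """No responsibility root qualifies at the requested alpha level."""


class InvalidInputError(ReceptorCallError):
    """Non-finite or otherwise malformed scalar input."""


class EmptyInputError(ReceptorCallError):
    """An operation received zero samples."""


class LengthMismatchError(ReceptorCallError):
    """Parallel per-sample sequences differ in length."""


class DuplicateSampleError(ReceptorCallError):
    """Duplicate sample or probe identifiers in a table."""


class SchemaError(ReceptorCallError):
    """File content does not match the expected schema (bad IHC token,
    non-numeric expression cell, missing column, ...)."""


class InvalidMatrixError(ReceptorCallError):
    """Reference expression matrix is ragged or otherwise unusable."""


class MissingProbeError(ReceptorCallError):
    """Requested probe absent from a sample or matrix."""


class InvalidConfigError(ReceptorCallError):
    """Simulation configuration field out of its allowed range."""
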