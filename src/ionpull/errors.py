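"""Exception hierarchy.

``ConfigurationError`` (and subclasses) are user errors — the CLI maps them
to exit code 1.  ``ConsistencyError`` flags an internal contradiction that
must never be silently clipped; the CLI maps it to exit code 2.
"""


class IonPullError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(IonPullError):
    """Invalid user-supplied configuration or parameters."""


class StabilityError(ConfigurationError):
    """The Langevin discretisation would be numerically unstable."""


class EmptyDataError(IonPullError):
    """An operation received no samples."""


class GridMismatchError(IonPullError):
    """Two profiles/archives do not share a common lambda grid."""


class ArchiveValidationError(IonPullError):
    """A pulling-run archive failed its internal audit (e.g. broken
    sequential-seeding chain, missing steps, hash mismatch)."""


class UndefinedConductanceError(IonPullError):
    """Mean work is zero within tolerance; conductance is undefined."""


class ConsistencyError(IonPullError):
    """An internal invariant was violated (e.g. negative total conductance
    with positive total work).  Raised, never clipped."""
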