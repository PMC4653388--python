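"""Exception hierarchy shared across the package."""


class CleftDockError(Exception):
    """Base class for all package errors."""


class InputError(CleftDockError):
    """A file or structure could not be read or is malformed."""


class EmptyStructureError(InputError):
    """No atoms survive parsing/filtering."""


class ConfigurationError(CleftDockError):
    """A run configuration is inconsistent or produces an empty setup."""


class ContinuationRefusedError(CleftDockError):
    """A simulation continuation was requested with changed non-GA parameters.

    Continuations are only valid when every parameter except the genetic
    algorithm parameters is unchanged; anything else invalidates the saved
    population.
    """


class StateError(CleftDockError):
    """A session-state file is corrupt or unreadable."""


class FixtureError(CleftDockError):
    """A synthetic fixture failed its generation-time certification."""
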