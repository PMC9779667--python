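"""Exception hierarchy shared across the pipeline.

Validation problems (bad configs, malformed tables) are distinguished from
runtime computation failures so the command-line layer can map them to
distinct exit codes.
"""


class SeedscreenError(Exception):
    """Base class for all package errors."""


class InputError(SeedscreenError, ValueError):
    """A caller-supplied value violates a documented precondition."""


class ConfigurationError(SeedscreenError, ValueError):
    """An inconsistent configuration (e.g. unresolved wild-type reference)."""


class PairingError(SeedscreenError, ValueError):
    """Mutant rows lack a same-plate/same-replicate wild-type cohort."""

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing or [])


class ComputationError(SeedscreenError, ArithmeticError):
    """A quantity is undefined for the given data (e.g. zero denominator)."""


class NotFoundSignal(SeedscreenError, LookupError):
    """A requested feature does not exist in the data (e.g. no elongated cell)."""
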