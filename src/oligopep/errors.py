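"""Exception hierarchy shared across the package."""


class OligopepError(Exception):
    """Base class for all package errors."""


class UnknownResidueError(OligopepError, KeyError):
    """A sequence uses a residue code absent from the residue table."""


class UnknownModificationError(OligopepError, KeyError):
    """A modification id is not present in the registry."""


class IncompatibleModificationError(OligopepError, ValueError):
    """A modification was placed on a residue it does not apply to."""


class EmptySequenceError(OligopepError, ValueError):
    """A molecule with no residues has no defined mass."""


class MissingComponentError(OligopepError, ValueError):
    """A conjugate references an oligo or peptide that was not supplied."""


class ChargeError(OligopepError, ValueError):
    """Charge states must be positive integers below the mass limit."""


class MatchingError(OligopepError, ValueError):
    """Peak-to-fragment matching was invoked with unusable inputs."""


class ProfileError(OligopepError, ValueError):
    """A cleavage profile could not be built or compared."""


class FitConvergenceError(OligopepError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class FitError(OligopepError, RuntimeError):
    """An optimizer failed or returned a boundary solution."""


class DataFormatError(OligopepError, ValueError):
    """An input table violates the expected dialect (named column/row)."""


class ConfigError(OligopepError, ValueError):
    """A run configuration is invalid or contains unknown keys."""
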