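"""Exception hierarchy shared across the package."""


class ModalignError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ModalignError, ValueError):
    """Malformed or inconsistent user input."""


class DegenerateModalityError(ModalignError, ValueError):
    """A modality whose distance vector is constant: correlation is undefined."""


class NoFeasibleSolutionError(ModalignError, RuntimeError):
    """No hyperparameter grid point satisfied the s/q constraints."""

    def __init__(self, message: str, best_primary_corr: float | None = None):
        super().__init__(message)
        self.best_primary_corr = best_primary_corr


class SolverError(ModalignError, RuntimeError):
    """The quadratic-program solver failed to converge."""
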