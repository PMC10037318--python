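"""Exception hierarchy.

Validation problems (bad files, bad config, contract violations) derive from
:class:`ValidationError`; numerical/iterative failures from
:class:`ComputeError`.  The CLI maps these to exit codes 2 and 3.
"""


class PepsurfError(Exception):
    """Base class for all package errors."""


class ValidationError(PepsurfError):
    """Bad input that can be diagnosed before (or without) any computation."""


class StructureError(ValidationError):
    """Malformed or inconsistent structure/trajectory files."""


class TopologyError(ValidationError):
    """A named atom or residue cannot be resolved in the topology."""


class ConfigurationError(ValidationError):
    """Missing or invalid configuration (tables, units, parameters)."""


class InputError(ValidationError):
    """An argument violates an operation's preconditions."""


class ComputeError(PepsurfError):
    """A computation failed (convergence, numeric overflow...)."""


class ConvergenceError(ComputeError):
    """An iterative solver did not reach tolerance within its budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class NumericError(ComputeError):
    """Overflow or an unnormalizable density."""
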