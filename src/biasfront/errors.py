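"""Exception hierarchy shared across the package.

Validation problems (bad parameters, malformed configs, inadmissible bias
values) raise :class:`ValidationError`; numerical failures of the speed
solver raise :class:`SolverError`.  The CLI maps these to exit codes 1 and 2.
"""


class BiasFrontError(Exception):
    """Base class for all package errors."""


class ValidationError(BiasFrontError, ValueError):
    """Invalid input: parameter out of its admissible range, bad config, ..."""


class SolverError(BiasFrontError, RuntimeError):
    """The minimization or the simulation could not produce a trustworthy answer."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        #: optional payload (e.g. the sampled objective curve) for post-mortem
        self.diagnostics = diagnostics
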