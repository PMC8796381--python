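"""Exception hierarchy shared across the package.

Exit-code mapping for the command line lives in :mod:`fluxscreen.cli`;
library code raises these types and never calls ``sys.exit``.
"""


class FluxscreenError(Exception):
    """Base class for all package-specific errors."""


class ModelValidationError(FluxscreenError):
    """A model violates a structural invariant (duplicate ids, dangling
    references, inverted bounds)."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class GprParseError(FluxscreenError):
    """Malformed gene-protein-reaction rule text.

    Carries the character ``offset`` at which parsing failed.
    """

    def __init__(self, message, offset):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class UnknownIdError(FluxscreenError, KeyError):
    """A reaction, metabolite, gene or member id is not present in the model."""

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)


class BoundsError(FluxscreenError, ValueError):
    """Lower bound exceeds upper bound."""


class FormatError(FluxscreenError):
    """A document does not conform to the expected file dialect."""


class UnsupportedDialectError(FormatError):
    """The file is recognizable but uses an unsupported dialect
    (e.g. SBML without the flux-balance-constraints package)."""


class NoObjectiveError(FluxscreenError):
    """An optimization was requested on a model with no objective anywhere."""


class InfeasibleModelError(FluxscreenError):
    """The base problem of a multi-solve analysis is infeasible or unbounded,
    so no per-task solve was attempted."""

    def __init__(self, message, status="infeasible"):
        super().__init__(message)
        self.status = status


class SolverEnvironmentError(FluxscreenError):
    """No usable LP backend is available."""


class ScreenConfigError(FluxscreenError):
    """Bad screening configuration: empty axis, unregistered analysis, ..."""
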