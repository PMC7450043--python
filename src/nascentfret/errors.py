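"""Exception hierarchy for the assay pipeline.

Every failure mode that carries scientific meaning (an unusable
experiment, an incomplete reaction quadruple, an infeasible fixture
inversion) gets its own class so callers can react precisely.
"""


class NascentFretError(Exception):
    """Base class for all package errors."""


class IncompleteQuadrupleError(NascentFretError):
    """A bundle is missing one or more of the D/DA/BD/BDA roles."""

    def __init__(self, missing_roles):
        self.missing_roles = tuple(sorted(missing_roles))
        super().__init__(
            "incomplete quadruple: missing role(s) "
            + ", ".join(self.missing_roles)
        )


class SpectrumGridError(NascentFretError):
    """An emission spectrum violates the 450-600 nm / 1 nm grid contract."""


class SchemaVersionError(NascentFretError):
    """A serialized bundle or results table has an unsupported schema."""


class UnusableExperimentError(NascentFretError):
    """A measurement cannot yield a FRET value (e.g. non-positive [RNC]).

    ``stage`` names the pipeline step that failed.
    """

    def __init__(self, message, stage):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class MissingConditionError(NascentFretError, KeyError):
    """A simulation was requested for a condition absent from the table."""


class InfeasibleInversionError(NascentFretError, ValueError):
    """Target apparent FRET cannot be realized at the requested stall ratio.

    Carries ``max_feasible_stall``, the largest stall ratio for which the
    per-chain FRET would still be <= 1.
    """

    def __init__(self, e_app, s, max_feasible_stall):
        self.e_app = e_app
        self.s = s
        self.max_feasible_stall = max_feasible_stall
        super().__init__(
            f"apparent FRET {e_app} at stall ratio {s} requires per-chain "
            f"FRET {e_app * (1 + s):.4f} > 1; max feasible stall ratio is "
            f"{max_feasible_stall:.4f}"
        )


class PairingError(NascentFretError, ValueError):
    """Bound/released profiles do not expose equivalent residue ranges."""


class ScenarioError(NascentFretError, ValueError):
    """A simulation/analysis scenario failed validation."""
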