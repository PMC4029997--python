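"""Exception hierarchy for adaptrex."""


class AdaptrexError(Exception):
    """Base class for all adaptrex errors."""


class InvalidArgumentError(AdaptrexError, ValueError):
    """An argument violates an operation's precondition."""


class InfeasibleConstraintError(AdaptrexError):
    """The geometric spacing constraint cannot be satisfied on the given bounds."""


class InsufficientDataError(AdaptrexError):
    """Not enough defined data points to perform the requested inversion."""


class InvalidStructureError(AdaptrexError):
    """A molecular structure is degenerate or malformed."""


class UndefinedMetricError(AdaptrexError):
    """A structural metric is undefined for the given inputs."""


class IncompleteTableError(AdaptrexError):
    """A score-table margin is missing required cells."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"score table is missing {len(self.missing)} cell(s): "
                         f"{self.missing[:8]}{'...' if len(self.missing) > 8 else ''}")


class NumericalBlowupError(AdaptrexError, FloatingPointError):
    """Integration produced a non-finite force or coordinate."""


class InvalidComparisonError(AdaptrexError):
    """Two run configurations differ in more than ladder mode and seed."""
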