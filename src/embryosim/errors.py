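"""Exception and warning types shared across the package."""


class EmbryosimError(Exception):
    """Base class for all package errors."""


class FormatError(EmbryosimError):
    """Malformed input table or file (bad header, duplicate names, bad values)."""


class StructureError(EmbryosimError):
    """Structurally invalid lineage tree (orphan parent, wrong child count)."""


class DegeneracyError(EmbryosimError):
    """Geometrically degenerate input (coincident positions, all-zero direction)."""


class ConvergenceError(EmbryosimError):
    """Energy minimization failed to reach the gradient tolerance.

    Carries the last iterate so callers can inspect or restart.
    """

    def __init__(self, message, positions=None, energy=None, grad_norm=None):
        super().__init__(message)
        self.positions = positions
        self.energy = energy
        self.grad_norm = grad_norm


class RolloutError(EmbryosimError):
    """Greedy policy rollout entered a loop or otherwise failed."""


class ConfigurationError(EmbryosimError):
    """Inconsistent simulation or environment configuration (e.g. unreachable goal)."""


class UnderdeterminedFitWarning(UserWarning):
    """Fit requested with too few observations to pin down the coefficients."""
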