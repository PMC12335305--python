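"""Exception hierarchy for the μPAD readout pipeline.

Exit-code mapping used by the CLI: configuration errors → 2,
segmentation failures → 3, fit failures → 4.
"""


class MuPadError(Exception):
    """Base class for all package-specific errors."""


class InputDomainError(MuPadError, ValueError):
    """An argument lies outside the operation's stated domain."""


class DegenerateInputError(InputDomainError):
    """Input is formally valid but carries no usable signal (e.g. a constant image)."""


class ConfigurationError(MuPadError):
    """An assay configuration or generator specification is inconsistent."""


class SegmentationError(MuPadError):
    """Fewer detection zones survived filtering than the layout expects."""

    def __init__(self, found: int, expected: int, message: str | None = None):
        self.found = found
        self.expected = expected
        super().__init__(
            message
            or f"segmentation found {found} candidate zone(s), expected {expected}"
        )


class RankDeficiencyError(MuPadError):
    """The calibration design has no usable degrees of freedom."""


class SensitivityZeroError(MuPadError):
    """Calibration slope is (numerically) zero; LOD/LOQ and inversion are undefined."""


class FlatTraceError(MuPadError):
    """Kinetic trace has no resolvable colour development above its noise floor."""


class FitFailureError(MuPadError):
    """The nonlinear optimiser failed to produce a converged fit."""
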